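# Methods

## The problem

High-throughput sequencing quantifies relative, not absolute, DNA
abundances. Trace quantities of exogenous DNA — from reagents, plasticware,
skin flora, food — compete with the sample's own molecules during library
preparation, so libraries prepared from dilute samples (single cells,
cell-free DNA, blanks) carry proportionally more contaminant-derived reads.
Reads that fail to map to the sample's reference genome but match other
genomes ("contaminant-matching reads") are intrinsically ambiguous: any one
read may come from a true contaminant molecule or from a sequencing error
that shifted a host read toward a homolog. `contamlens` therefore never
attributes individual reads; it characterizes the population of
contaminant-matching reads per library and tests whether their behavior is
consistent with contamination.

## The mass-competition model

The pipeline's quantitative backbone is a competition model: a fixed
contaminant mass `c` (pg) competes with sample input mass `m` (pg), so the
probability that a sequenced fragment is contaminant-derived is

    p(m) = c / (c + m)

and on the logit scale

    logit p(m) = ln c − ln m.

A binomial GLM of per-library contaminant hit counts on `ln m` (logit link)
therefore has true slope **−1**; the fitted slope, its Wald z and p quantify
the inverse relationship between sample concentration and contamination.
The GLM is fitted by iteratively reweighted least squares (deviance-change
tolerance 1e-8, at most 100 iterations, standard errors from the observed
information matrix). Separation or non-convergence is flagged on the result
rather than raised; inference is Wald (matching the z statistic convention),
not likelihood-ratio. Natural logs throughout: Pearson correlations and GLM
fits are base-invariant, but the intercept estimates `ln c` and is reported
on that scale.

## Pipeline stages

1. **Host screening** (`alignment.screen_host`). A bowtie-1-style ungapped
   seeded aligner: the first 28 bases form the seed; the permissive screen
   allows up to 3 seed mismatches and (by default) 2 mismatches outside the
   seed, approximating the default quality-ceiling of `-n`-mode alignment at
   high base quality. Candidate loci come from a pigeonhole word index (the
   seed split into four disjoint 7-mers: any placement with ≤3 seed
   mismatches leaves at least one word exact, so the search is lossless);
   candidates are verified by vectorized Hamming comparison. `N` never
   participates in words and mismatches everything. Any placement at all
   counts as "mapped" — deliberately permissive, to keep contaminant
   inference conservative.

2. **Paired alternate-genome criterion** (`alignment.paired_alt_fraction`).
   A read pair is a contaminant hit iff both ends fail the permissive
   primary screen, both ends map to the alternate genome with **no seed
   mismatches**, and two placements fall on the same reference within 1 kb.
   Orientation and mate order are ignored (the published criterion does not
   state them); the window and mismatch policies are configurable.

3. **Perfect-match classification** (`alignment.perfect_matches`,
   `classification.assign_read`). Surviving reads are searched against a
   candidate-contaminant database for contiguous, N-free, 100%-identity
   matches of at least `L` bases. `L` is per-dataset (published analyses
   used 48/75/40/101 for 48/75/56-trimmed-to-41/101-bp reads); the engine
   anchors on shared 16-mers with bidirectional extension and is lossless
   for `L ≥ 16`. All matching subjects are reported (no report cap): with
   the multi-category discard rule below, exhaustive reporting is strictly
   more conservative; a cap remains available for replication of
   cap-limited searches.

   Each matched taxon is mapped to a coarse **category**: its ancestor at
   depth 4 from the taxonomy root (root = depth 1), or the nearest ancestor
   at a named rank (e.g. `genus`) for the blank comparison. Depth-4
   categories are broad clades (phylum/class level — Streptophyta,
   Chordata, ...), which is the granularity at which conserved-sequence
   misassignment is tolerable. Nodes shallower than the requested depth map
   to themselves.

   Discard rules, applied in a fixed order (no hits → unresolvable taxids →
   host species → only-unclassifiable → multiple categories): the order is a
   design choice; the rules themselves are standard. Hits to placeholder
   taxa (names containing "uncultured", "unclassified", "unidentified",
   "environmental sample", "metagenome"; configurable, ancestors included)
   are dropped when classifiable hits coexist and cause an
   `unclassifiable` discard otherwise. In rank mode a read whose matches
   all lack the requested rank is likewise discarded as `unclassifiable` —
   the read cannot be placed at the requested level. Per-million
   frequencies are measured against the **pre-screening** library size.

4. **Blank concordance** (`statistics.blank_concordance`). Genus-level
   count profiles of the pooled positive and pooled blank (no-input
   negative control) libraries are compared as `ln(count + 1)` vectors over
   the union of observed genera (the pseudocount keeps genera absent from
   one pool in the comparison) via Pearson correlation. Matched
   positive/blank pools from one experiment should correlate much better
   than pools from different experiments.

5. **Targeted screen** (`targeted_screen`). Host-unmapped reads are mapped
   strictly (0 seed mismatches) against a small panel of target genomes
   (e.g. chloroplasts). Two filters follow. *Cross-database rescreening*:
   a read is removed when its longest exact match to any non-target
   sequence in a broader labelled database is at least as long as its
   longest exact match to the assigned target (ties remove — conservative;
   an exact-length comparison stands in for alignment-score comparison
   because the engine is exact-match based). *Coverage evenness*: per
   genome, the share of all aligned bases falling in the single
   most-covered 1-kb window; a genome fails above 0.5. The constants are
   heuristics for the visual criterion "reads pile onto one locus"
   (low-complexity artifacts) versus genome-wide spread; both are
   configurable, and the property that matters — planted pile-ups fail,
   uniform coverage passes — holds across a wide band of settings.

6. **Heatmap clustering** (`statistics.neighbor_joining`,
   `heatmap_matrix`). Genomes with fewer than 200 hits across samples are
   dropped; remaining counts become `ln(count+1)`; rows and columns are
   ordered by depth-first traversal of classical neighbor-joining trees
   (Saitou–Nei Q-criterion, lowest-index tie-break) over Euclidean
   distances between the transformed vectors. The distance metric is a
   design choice (only the algorithm is conventionally fixed); NJ on any
   additive matrix reproduces the generating tree metric exactly, which the
   tests verify to 1e-9. Fewer than 3 rows or columns returns the axis
   unclustered with a flag.

## The synthetic-data generator

`synthetic_data` generates the study conditions under which the pipeline is
validated; every emitted read carries its true origin.

* **Taxonomy**: random rooted trees of uniform depth (default 6), ranks
  assigned by depth with `genus` and `species` fixed as the last two
  levels; leaves are species. Emitted in the taxdump dialect and
  round-tripped by the parser.
* **Genomes**: i.i.d. uniform ACGT (GC 0.5), one per species plus an
  independent host. Distinct genomes share essentially no substrings at
  the perfect-match threshold (expected shared 26-mers between two 50-kb
  genomes ≈ 1e-6), so cross-matches cannot arise by chance at pipeline
  scale. Contamination is modeled at the mass-fraction level, ignoring
  genome-size weighting (the competition argument is in DNA mass);
  size-weighting can be layered on by scaling the per-species masses.
* **Libraries**: per-read origins drawn independently with probability
  `c_s/(m+Σc_s)` per species; uniform start positions (fragment-based for
  pairs, default 300-bp templates); substitution-only errors (no indels —
  matching the ungapped/exact inference engines), default rate 0.1%
  (typical Illumina); constant Q37 qualities (qualities are not used by
  inference). Blanks are libraries with `m = 0`.
* **Dilution series**: one paired library per input mass
  (default 10⁶/10³/10²/10 pg), constant contaminant mass `c = 0.02` pg —
  chosen so that the most concentrated library yields only a handful of
  contaminant pairs while the most dilute yields a few parts per thousand,
  the regime reported for real dilution experiments (≈175 contaminant reads
  per million at 100 pg input implies c ≈ 0.02 pg). The series defaults to
  error rate 0 because it isolates the mass-competition mechanism, under
  which the paired-hit count equals the truth table exactly and the GLM
  slope is −1 by construction; error-rate and mass parameters are exposed.
* **Genus profiles** for the blank comparison: Dirichlet-multinomial draws
  (40 genera, concentration 0.3 — a few dominant genera with a long sparse
  tail, the shape of real contaminant spectra), positive pools of 50,000
  reads against blank pools of 500 (blanks in the reanalyzed experiments
  yielded 0.2–0.6% of the positive read count). Matched pairs share one
  proportion vector; mismatched pairs draw independent vectors.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: platform-specific error profiles and indels,
amplification and coverage bias, homology between contaminant and host
genomes (real misassignment pressure comes from conserved sequence, absent
here by construction), database incompleteness, and index-hopping between
multiplexed libraries. The synthetic validation establishes that the
machinery is correct under its stated model, not that the model captures
every property of real libraries.

## Validation problem sizes

The shipped validation suite runs the full dilution pipeline at 100,000
pairs per library over four masses (slope recovered within 2 standard
errors of −1); classifier truth recovery on 3 libraries × 2,000 reads of
length 36 with 10 species under a depth-6 taxonomy (exact count recovery at
error rate 0; recall ≥ 0.9 at 0.5% errors with L = 26); engine/brute-force
equivalence on 1,000 reads against a 50-kb genome and 500 reads against a
20-sequence database; 200 replicates of the matched/mismatched blank
contrast; 50 seeds of evenness discrimination; and 20 random GLM datasets
against an independent Newton–Raphson oracle (agreement to 6 significant
figures). The read length of 36 bp for the classifier study matches
early-generation instruments and keeps the stated error-rate/recall
operating point self-consistent: with substitution rate e per base, the
chance a read of length R retains an error-free run of ≥ L bases is
(1−e)^L · (1 + (R−L)e), which at e = 0.005, R = 36, L = 26 is ≈ 0.92, but
falls to ≈ 0.67 at R = 101 — near-full-length matching of long reads is
only viable at much lower error rates.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally, 1-based closed in
human-readable outputs. Reads shorter than the seed (aligner) or than `L`
(exact engine) are contract errors; libraries with zero reads produce a
zero row and a warning; zero-hit genomes pass evenness trivially but are
flagged uninformative; a constant log-count vector leaves the concordance
undefined (NaN, flagged) rather than raising. Subsampling treats mate
pairs as atomic units and returns the largest whole-unit subset within the
cap. NJ ties break toward the lowest index pair so results are
deterministic; all generators are pure functions of their seed.

## Known limitations

The aligner is ungapped and substitution-only by design; it is not a
general-purpose mapper and does not scale to mammalian genomes (the
validation suite uses tens-of-kilobase references). The exact-match engine
replaces score-based database search with a longest-exact-match criterion,
which is stricter and slightly more conservative near the length threshold.
The unclassifiable-name pattern list is heuristic. Desk-scale validation
numbers (counts, z statistics) are necessarily smaller in magnitude than
those obtainable from multi-gigabyte public datasets; the mechanisms, not
the magnitudes, are what the suite pins down.
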