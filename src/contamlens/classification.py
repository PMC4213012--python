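"""Per-read taxonomic assignment and per-sample category count profiles.

A read that survives host screening and has perfect matches in the candidate
database is assigned to a single coarse taxonomic category (the matched
taxa's ancestor at a fixed depth from the root, or at a named rank).  Reads
whose matches span more than one category are discarded — conserved sequence
is uninformative for classification — as are reads matching the host
species, matching only unclassifiable database records, or whose matches
carry no resolvable taxon id.

Also houses read preprocessing: per-position entropy (to locate barcode /
adapter prefixes), prefix trimming and pair-aware uniform subsampling.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import ExactMatchIndex, GenomeIndex, PerfectHit, ReadRecord, perfect_matches, screen_host
from .taxonomy import DEFAULT_UNCLASSIFIABLE_PATTERNS, TaxonomyTree

__all__ = [
    "AssignmentOutcome",
    "CategoryCountMatrix",
    "PipelineConfig",
    "DISCARD_REASONS",
    "assign_read",
    "profile_samples",
    "positional_entropy",
    "trim_prefix",
    "subsample_reads",
]

logger = logging.getLogger(__name__)

DISCARD_REASONS = ("no_hit", "no_taxid", "host_species", "unclassifiable", "multi_category")


@dataclass(frozen=True)
class AssignmentOutcome:
    """Per-read classification: a category taxon OR a discard reason."""

    read_id: str
    status: str  # "assigned" | "discarded"
    category: int | None = None
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.status == "assigned" and (self.category is None or self.reason is not None):
            raise ValueError("assigned outcome must carry a category and no reason")
        if self.status == "discarded" and (
            self.reason not in DISCARD_REASONS or self.category is not None
        ):
            raise ValueError(f"discarded outcome must carry a reason from {DISCARD_REASONS}")


@dataclass
class PipelineConfig:
    """Fixed thresholds of the profiling pipeline.

    ``min_match_length`` is the perfect-match length L; published analyses of
    48/75/40/101-bp datasets used L equal to (close to) the usable read
    length.  ``level`` places categories at a depth from the taxonomy root
    (root = 1); setting ``rank`` (e.g. ``"genus"``) switches to rank-based
    assignment.
    """

    min_match_length: int = 40
    level: int = 4
    rank: str | None = None
    host_seed_mismatches: int = 3
    target_seed_mismatches: int = 0
    max_other_mismatches: int = 2
    pair_window: int = 1000
    trim_prefix: int = 15
    subsample_cap: int = 7_500_000
    heatmap_min_hits: int = 200
    pseudocount: int = 1

    def __post_init__(self) -> None:
        for name in (
            "min_match_length",
            "level",
            "pair_window",
            "subsample_cap",
            "heatmap_min_hits",
            "pseudocount",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class CategoryCountMatrix:
    """Samples x taxonomic-category contaminant-read counts with totals.

    ``totals`` are pre-screening library sizes, so per-million frequencies
    are measured against the whole experiment, not the unmapped remainder.
    """

    def __init__(self, counts: pd.DataFrame, totals: pd.Series):
        counts = counts.astype(int)
        totals = totals.astype(int).reindex(counts.index)
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative category counts")
        if (counts.sum(axis=1) > totals).any():
            raise ValueError("category counts exceed per-sample totals")
        self.counts = counts
        self.totals = totals

    @property
    def samples(self) -> list:
        return list(self.counts.index)

    @property
    def categories(self) -> list:
        return list(self.counts.columns)

    def per_million(self) -> pd.DataFrame:
        return self.counts.div(self.totals, axis=0) * 1e6

    def pooled(self) -> tuple[pd.Series, int]:
        """Sum counts and totals across samples."""
        return self.counts.sum(axis=0), int(self.totals.sum())

    def __add__(self, other: "CategoryCountMatrix") -> "CategoryCountMatrix":
        counts = self.counts.add(other.counts, fill_value=0).astype(int)
        totals = self.totals.add(other.totals, fill_value=0).astype(int)
        return CategoryCountMatrix(counts, totals)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out["total_reads"] = self.totals
        out.to_csv(path, sep="\t", index_label="sample")


def assign_read(
    read_id: str,
    hits: Sequence[PerfectHit],
    tree: TaxonomyTree,
    host_taxon: int,
    level: int = 4,
    rank: str | None = None,
    unclassifiable_patterns: Iterable[str] = DEFAULT_UNCLASSIFIABLE_PATTERNS,
) -> AssignmentOutcome:
    """Classify one read from its perfect hits.

    Discard rules, applied in order:

    1. no hits at all -> ``no_hit``;
    2. hits whose taxon id did not resolve are dropped; if that removes
       everything -> ``no_taxid``;
    3. any hit to the host species (or a descendant) -> ``host_species``;
    4. hits to unclassifiable taxa are dropped; if only such hits existed ->
       ``unclassifiable``;
    5. remaining taxa are mapped to categories (ancestor at ``level``, or at
       ``rank`` when given — taxa with no such rank ancestor are dropped, and
       a read left with none is discarded as ``unclassifiable``); more than
       one distinct category -> ``multi_category``, exactly one -> assigned.
    """
    if not hits:
        return AssignmentOutcome(read_id, "discarded", reason="no_hit")
    taxids = [h.subject_taxid for h in hits if h.subject_taxid is not None]
    if not taxids:
        return AssignmentOutcome(read_id, "discarded", reason="no_taxid")
    if any(tree.descends_from(t, host_taxon) for t in taxids):
        return AssignmentOutcome(read_id, "discarded", reason="host_species")
    classifiable = [
        t for t in taxids if not tree.is_unclassifiable(t, unclassifiable_patterns)
    ]
    if not classifiable:
        return AssignmentOutcome(read_id, "discarded", reason="unclassifiable")
    if rank is not None:
        categories = {
            c for t in classifiable if (c := tree.rank_ancestor(t, rank)) is not None
        }
        if not categories:
            return AssignmentOutcome(read_id, "discarded", reason="unclassifiable")
    else:
        categories = {tree.ancestor_at_level(t, level) for t in classifiable}
    if len(categories) > 1:
        return AssignmentOutcome(read_id, "discarded", reason="multi_category")
    return AssignmentOutcome(read_id, "assigned", category=categories.pop())


def profile_samples(
    libraries: Mapping[str, Sequence[ReadRecord]],
    host_index: GenomeIndex,
    db_index: ExactMatchIndex,
    tree: TaxonomyTree,
    host_taxon: int,
    config: PipelineConfig | None = None,
) -> tuple[CategoryCountMatrix, dict[str, list[AssignmentOutcome]]]:
    """Run host screen -> perfect-match search -> assignment per sample.

    Returns the category count matrix (totals = pre-screening library sizes)
    and the per-sample assignment outcomes (host-mapped reads excluded; the
    accounting invariant is host_mapped + assigned + discarded = total).
    """
    if not libraries:
        raise ValueError("profile_samples requires at least one library")
    cfg = config or PipelineConfig()
    rows: dict[str, Counter] = {}
    totals: dict[str, int] = {}
    outcomes: dict[str, list[AssignmentOutcome]] = {}
    for sample, reads in libraries.items():
        totals[sample] = len(reads)
        rows[sample] = Counter()
        outcomes[sample] = []
        if not reads:
            logger.warning("sample %s has zero reads", sample)
            continue
        _, unmapped = screen_host(
            reads,
            host_index,
            max_seed_mismatches=cfg.host_seed_mismatches,
            max_other_mismatches=cfg.max_other_mismatches,
        )
        for read in unmapped:
            if len(read.sequence) < cfg.min_match_length:
                outcome = AssignmentOutcome(read.read_id, "discarded", reason="no_hit")
            else:
                hits = perfect_matches(db_index, read, cfg.min_match_length)
                outcome = assign_read(
                    read.read_id, hits, tree, host_taxon, level=cfg.level, rank=cfg.rank
                )
            outcomes[sample].append(outcome)
            if outcome.status == "assigned":
                rows[sample][outcome.category] += 1
    categories = sorted({c for row in rows.values() for c in row})
    counts = pd.DataFrame(
        [[rows[s].get(c, 0) for c in categories] for s in libraries],
        index=list(libraries),
        columns=categories,
    )
    matrix = CategoryCountMatrix(counts, pd.Series(totals))
    return matrix, outcomes


def positional_entropy(reads: Sequence[ReadRecord]) -> np.ndarray:
    """Shannon entropy (bits) of base composition at each read position.

    N bases are excluded from the frequencies; positions beyond a read's
    length are ignored for that read.  Useful for spotting low-information
    library prefixes (barcodes, template-switch guanines) worth trimming.
    """
    if not reads:
        raise ValueError("positional_entropy requires at least one read")
    max_len = max(len(r.sequence) for r in reads)
    counts = np.zeros((max_len, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for r in reads:
        for p, b in enumerate(r.sequence):
            i = base_idx.get(b.upper())
            if i is not None:
                counts[p, i] += 1
    tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(tot > 0, counts / np.maximum(tot, 1), 0.0)
        terms = np.where(f > 0, -f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    return terms.sum(axis=1)


def trim_prefix(reads: Sequence[ReadRecord], k: int = 15) -> list[ReadRecord]:
    """Remove the first ``k`` bases (and qualities) of each read.

    Reads of length <= k are dropped; the dropped count is logged.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return list(reads)
    out: list[ReadRecord] = []
    dropped = 0
    for r in reads:
        if len(r.sequence) <= k:
            dropped += 1
            continue
        out.append(
            ReadRecord(
                read_id=r.read_id,
                sequence=r.sequence[k:],
                quality=r.quality[k:] if r.quality is not None else None,
                mate=r.mate,
                library_id=r.library_id,
            )
        )
    if dropped:
        logger.info("trim_prefix dropped %d reads of length <= %d", dropped, k)
    return out


def subsample_reads(
    reads: Sequence[ReadRecord], cap: int, seed: int
) -> list[ReadRecord]:
    """Uniform random subsample of at most ``cap`` reads, reproducible by seed.

    Paired mates (records sharing a read id) are kept or dropped together;
    with paired data the result is the largest whole-pair subset not
    exceeding the cap.  Input order is preserved.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if len(reads) <= cap:
        return list(reads)
    groups: dict[str, list[int]] = defaultdict(list)
    order: list[str] = []
    for i, r in enumerate(reads):
        if r.read_id not in groups:
            order.append(r.read_id)
        groups[r.read_id].append(i)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(order))
    keep: set[int] = set()
    n = 0
    for gi in perm:
        members = groups[order[gi]]
        if n + len(members) > cap:
            continue
        keep.update(members)
        n += len(members)
        if n == cap:
            break
    return [r for i, r in enumerate(reads) if i in keep]
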