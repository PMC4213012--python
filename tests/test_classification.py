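import numpy as np
import pandas as pd
import pytest

from contamlens.alignment import GenomeIndex, PerfectHit, ReadRecord, build_exact_index
from contamlens.classification import (
    CategoryCountMatrix,
    PipelineConfig,
    assign_read,
    positional_entropy,
    profile_samples,
    subsample_reads,
    trim_prefix,
)
from contamlens.synthetic_data import (
    LibrarySpec,
    simulate_genomes,
    simulate_library,
    simulate_taxonomy,
)

HOST_TAXON = 12  # Homo sapiens in the small_tree fixture


def hit(taxid, read_id="r", length=48):
    return PerfectHit(read_id, f"seq_{taxid}", taxid, length, "+", 0)


class TestAssignRead:
    def test_no_hits(self, small_tree):
        out = assign_read("r", [], small_tree, HOST_TAXON)
        assert (out.status, out.reason) == ("discarded", "no_hit")

    def test_all_taxids_unresolved(self, small_tree):
        hits = [PerfectHit("r", "s", None, 48, "+", 0)]
        out = assign_read("r", hits, small_tree, HOST_TAXON)
        assert out.reason == "no_taxid"

    def test_host_species_hit_discards_whole_read(self, small_tree):
        out = assign_read("r", [hit(7), hit(12)], small_tree, HOST_TAXON)
        assert out.reason == "host_species"
        # descendants of the host taxon count as host too
        out = assign_read("r", [hit(12)], small_tree, host_taxon=10)
        assert out.reason == "host_species"

    def test_only_unclassifiable_hits(self, small_tree):
        out = assign_read("r", [hit(21)], small_tree, HOST_TAXON)
        assert out.reason == "unclassifiable"

    def test_unclassifiable_hits_dropped_when_classifiable_coexist(self, small_tree):
        out = assign_read("r", [hit(21), hit(7)], small_tree, HOST_TAXON)
        assert out.status == "assigned" and out.category == 4

    def test_same_category_species_assigned_to_shared_ancestor(self, small_tree):
        # both species sit under the depth-4 node 9 (Mammalia); host is elsewhere
        out = assign_read("r", [hit(14), hit(14)], small_tree, host_taxon=7)
        assert out.status == "assigned" and out.category == 9

    def test_two_categories_discarded(self, small_tree):
        out = assign_read("r", [hit(7), hit(14)], small_tree, host_taxon=21)
        assert out.reason == "multi_category"

    def test_rank_mode_genus(self, small_tree):
        out = assign_read("r", [hit(7)], small_tree, HOST_TAXON, rank="genus")
        assert out.status == "assigned" and out.category == 6
        out = assign_read("r", [hit(12), hit(14)], small_tree, host_taxon=7, rank="genus")
        assert out.reason == "multi_category"

    def test_rank_mode_no_rank_ancestor_discards(self, small_tree):
        # node 23 has no genus in its lineage
        out = assign_read("r", [hit(23)], small_tree, HOST_TAXON, rank="genus")
        assert out.status == "discarded"


@pytest.fixture(scope="module")
def truth_world():
    """Ten contaminant species with genomes, host and taxonomy."""
    tree, species = simulate_taxonomy(seed=51, n_species=10, depth=6)
    host, genomes = simulate_genomes(species, seed=52)
    host_index = GenomeIndex({"host": host})
    db = {f"seq_{t}": g for t, g in genomes.items()}
    db_index = build_exact_index(db, {f"seq_{t}": t for t in genomes}, min_match=26)
    host_taxon = tree.root_id  # synthetic host genome is outside the tree; use a
    # taxon that no contaminant descends from
    return tree, species, host, genomes, host_index, db_index


class TestProfileSamples:
    def test_pure_host_library_gives_zero_row(self, truth_world):
        tree, species, host, genomes, host_index, db_index = truth_world
        reads = [ReadRecord(f"r{i}", host[i * 50 : i * 50 + 36]) for i in range(100)]
        cfg = PipelineConfig(min_match_length=26)
        matrix, outcomes = profile_samples(
            {"s": reads}, host_index, db_index, tree, species[0] * 10**6, cfg
        )
        assert matrix.counts.loc["s"].sum() == 0 if len(matrix.categories) else True
        assert int(matrix.totals.loc["s"]) == 100

    def test_error_free_counts_equal_truth(self, truth_world):
        tree, species, host, genomes, host_index, db_index = truth_world
        libraries = {}
        truths = {}
        for i in range(2):
            spec = LibrarySpec(f"lib{i}", 100.0, {t: 5.0 for t in species}, 800)
            reads, truth = simulate_library(
                spec, host, genomes, seed=60 + i, read_length=36, error_rate=0.0
            )
            libraries[spec.name] = reads
            truths[spec.name] = truth
        cfg = PipelineConfig(min_match_length=26)
        # synthetic host genome has no taxon in the tree; use an id outside it
        matrix, outcomes = profile_samples(
            libraries, host_index, db_index, tree, host_taxon=999999, config=cfg
        )
        for name, truth in truths.items():
            expected = {}
            for t, n in truth.realized_counts.items():
                if t == 0:
                    continue
                cat = tree.ancestor_at_level(t, 4)
                expected[cat] = expected.get(cat, 0) + n
            got = {c: int(matrix.counts.loc[name, c]) for c in matrix.categories}
            got = {c: v for c, v in got.items() if v}
            assert got == expected

    def test_conservation_invariant(self, truth_world):
        tree, species, host, genomes, host_index, db_index = truth_world
        spec = LibrarySpec("lib", 100.0, {t: 5.0 for t in species}, 500)
        reads, _ = simulate_library(
            spec, host, genomes, seed=71, read_length=36, error_rate=0.005
        )
        cfg = PipelineConfig(min_match_length=26)
        matrix, outcomes = profile_samples(
            {"lib": reads}, host_index, db_index, tree, 999999, cfg
        )
        outs = outcomes["lib"]
        host_mapped = len(reads) - len(outs)
        assigned = sum(o.status == "assigned" for o in outs)
        discarded = sum(o.status == "discarded" for o in outs)
        assert host_mapped + assigned + discarded == len(reads)
        assert assigned == int(matrix.counts.loc["lib"].sum())

    def test_pooling_equals_summing_rows(self, truth_world):
        tree, species, host, genomes, host_index, db_index = truth_world
        cfg = PipelineConfig(min_match_length=26)
        libs = {}
        for i in range(2):
            spec = LibrarySpec(f"p{i}", 100.0, {t: 5.0 for t in species}, 300)
            libs[spec.name], _ = simulate_library(
                spec, host, genomes, seed=80 + i, read_length=36, error_rate=0.0
            )
        m_split, _ = profile_samples(libs, host_index, db_index, tree, 999999, cfg)
        m_pooled, _ = profile_samples(
            {"pool": libs["p0"] + libs["p1"]}, host_index, db_index, tree, 999999, cfg
        )
        pooled_counts, pooled_total = m_split.pooled()
        assert pooled_total == int(m_pooled.totals.loc["pool"])
        for c in m_pooled.categories:
            assert int(pooled_counts.get(c, 0)) == int(m_pooled.counts.loc["pool", c])

    def test_database_growth_never_creates_new_assignments(self, truth_world):
        """Adding sequences can only move reads toward multi_category/host."""
        tree, species, host, genomes, host_index, db_index = truth_world
        spec = LibrarySpec("lib", 100.0, {t: 5.0 for t in species}, 300)
        reads, _ = simulate_library(
            spec, host, genomes, seed=90, read_length=36, error_rate=0.0
        )
        cfg = PipelineConfig(min_match_length=26)
        _, out_small = profile_samples(
            {"lib": reads}, host_index, db_index, tree, 999999, cfg
        )
        # enlarge the db with copies of every genome under taxa from the OTHER clade
        other = {f"dup_{t}": g for t, g in genomes.items()}
        taxmap = {f"seq_{t}": t for t in genomes}
        # assign each duplicate to a species whose level-4 category differs, if any
        cats = {t: tree.ancestor_at_level(t, 4) for t in species}
        for t in genomes:
            donor = next((u for u in species if cats[u] != cats[t]), t)
            taxmap[f"dup_{t}"] = donor
        big_db = {f"seq_{t}": g for t, g in genomes.items()} | other
        big_index = build_exact_index(big_db, taxmap, min_match=26)
        _, out_big = profile_samples(
            {"lib": reads}, host_index, big_index, tree, 999999, cfg
        )
        small = {o.read_id: o for o in out_small["lib"]}
        big = {o.read_id: o for o in out_big["lib"]}
        for rid, o_small in small.items():
            o_big = big[rid]
            if o_big.status == "assigned":
                # a read assigned under the big db was not multi-category before
                assert small[rid].reason != "multi_category"


class TestPreprocessing:
    def test_entropy_constant_position_is_zero(self):
        reads = [ReadRecord(f"r{i}", "GACT") for i in range(10)]
        ent = positional_entropy(reads)
        assert ent[0] == 0.0

    def test_entropy_uniform_position_is_two_bits(self):
        reads = [ReadRecord(f"r{i}", b) for i, b in enumerate("ACGT")]
        assert positional_entropy(reads)[0] == pytest.approx(2.0)

    def test_entropy_empty_input_rejected(self):
        with pytest.raises(ValueError):
            positional_entropy([])

    def test_barcode_prefix_depresses_entropy(self, rng):
        """Barcode+GGG prefixes show low entropy that recovers downstream."""
        barcodes = ["ACACAC", "GTGTGT", "CAGTCA", "TTGGAA"]
        reads = []
        for i in range(400):
            bc = barcodes[i % 4]
            tail = "".join(rng.choice(list("ACGT"), size=30))
            reads.append(ReadRecord(f"r{i}", bc + "GGG" + tail))
        ent = positional_entropy(reads)
        assert ent[:9].mean() < 1.5
        assert ent[9:].mean() > 1.9

    def test_trim_identity_at_zero(self):
        reads = [ReadRecord("r", "ACGTACGT", "IIIIIIII")]
        assert trim_prefix(reads, 0) == reads

    def test_trim_fifteen_of_fiftysix(self):
        seq = "A" * 15 + "C" * 41
        out = trim_prefix([ReadRecord("r", seq, "I" * 56)], 15)
        assert out[0].sequence == "C" * 41 and len(out[0].quality) == 41

    def test_trim_drops_short_reads(self):
        out = trim_prefix([ReadRecord("r", "ACGTACGTAC")], 15)
        assert out == []

    def test_subsample_under_cap_is_identity(self):
        reads = [ReadRecord(f"r{i}", "ACGT") for i in range(100)]
        assert subsample_reads(reads, 1000, seed=1) == reads

    def test_subsample_deterministic(self):
        reads = [ReadRecord(f"r{i}", "ACGT") for i in range(10_000)]
        a = subsample_reads(reads, 1000, seed=5)
        b = subsample_reads(reads, 1000, seed=5)
        assert [r.read_id for r in a] == [r.read_id for r in b]
        assert len(a) == 1000

    def test_subsample_keeps_mates_together(self):
        reads = []
        for i in range(500):
            reads.append(ReadRecord(f"p{i}", "ACGT", mate=1))
            reads.append(ReadRecord(f"p{i}", "TTTT", mate=2))
        out = subsample_reads(reads, 100, seed=2)
        from collections import Counter

        counts = Counter(r.read_id for r in out)
        assert all(v == 2 for v in counts.values())
        assert len(out) == 100

    def test_subsample_uniformity(self, rng):
        """Selection frequencies uniform within 3 sigma over repeated draws."""
        reads = [ReadRecord(f"r{i}", "ACGT") for i in range(20)]
        n_trials = 1000
        counts = np.zeros(20)
        for t in range(n_trials):
            for r in subsample_reads(reads, 10, seed=t):
                counts[int(r.read_id[1:])] += 1
        p = 0.5
        sigma = np.sqrt(n_trials * p * (1 - p))
        assert np.all(np.abs(counts - n_trials * p) < 3 * sigma)


class TestCategoryCountMatrix:
    def test_per_million(self):
        counts = pd.DataFrame({10: [5], 20: [0]}, index=["s"])
        m = CategoryCountMatrix(counts, pd.Series({"s": 1_000_000}))
        assert m.per_million().loc["s", 10] == 5.0

    def test_counts_cannot_exceed_totals(self):
        counts = pd.DataFrame({10: [5]}, index=["s"])
        with pytest.raises(ValueError):
            CategoryCountMatrix(counts, pd.Series({"s": 3}))
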