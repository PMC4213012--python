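"""Synthetic taxonomies, genomes and sequencing libraries with known truth.

The generator embodies the contamination model the analysis assumes: a fixed
mass c_s (pg) of each contaminant species' DNA competes with the sample's
input mass m (pg) during library preparation, so each read independently
originates from species s with probability c_s / (m + Σc_s) and from the
host otherwise (mass-competition model).  Blank (negative-control) libraries
have m = 0: every read is contaminant-derived.  Genomes are i.i.d. uniform
ACGT, so distinct genomes share essentially no k-mers of length >= 16 and
cross-matches are vanishingly improbable; sequencing error is
substitution-only, matching the ungapped/exact-match inference engines.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import ReadRecord, revcomp
from .taxonomy import TaxonNode, TaxonomyTree

__all__ = [
    "LibrarySpec",
    "SimulationTruth",
    "simulate_taxonomy",
    "simulate_genomes",
    "simulate_library",
    "simulate_dilution_series",
    "simulate_genus_profile_pair",
]

HOST_ORIGIN = 0  # truth-table code for host-derived reads

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# rank labels assigned by depth; the last two are always genus and species
_INTERMEDIATE_RANKS = ["superkingdom", "kingdom", "phylum", "class", "order", "family"]


@dataclass(frozen=True)
class LibrarySpec:
    """One library: input mass m (pg), per-species contaminant masses (pg)."""

    name: str
    input_mass: float
    contaminant_masses: Mapping[int, float]
    n_reads: int
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.input_mass < 0 or any(c < 0 for c in self.contaminant_masses.values()):
            raise ValueError("masses must be non-negative")
        if self.is_blank and self.input_mass != 0:
            raise ValueError("blank libraries have zero input mass")

    @property
    def expected_contaminant_fraction(self) -> float:
        c = sum(self.contaminant_masses.values())
        return c / (c + self.input_mass)


@dataclass
class SimulationTruth:
    """Per-read true origin and per-library composition."""

    origins: dict[str, int]  # (read id) -> species taxid, or HOST_ORIGIN
    realized_counts: dict[int, int]  # origin -> number of fragments
    expected_contaminant_fraction: float

    def contaminant_read_ids(self) -> set[str]:
        return {rid for rid, o in self.origins.items() if o != HOST_ORIGIN}


def simulate_taxonomy(
    seed: int, n_species: int = 10, depth: int = 6
) -> tuple[TaxonomyTree, list[int]]:
    """Random rooted taxonomy of uniform depth with rank labels by depth.

    Leaves (rank "species") all sit at ``depth``; their parents have rank
    "genus"; intermediate depths carry standard rank labels.  Requires
    depth >= 5 so that level-4 categories are non-trivial.  Returns the tree
    and the species taxon ids.
    """
    if depth < 5:
        raise ValueError("depth must be >= 5")
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    # node counts per depth grow geometrically from 1 (root) to n_species
    level_sizes = [1]
    for k in range(2, depth):
        level_sizes.append(
            int(max(1, min(n_species, round(n_species ** ((k - 1) / (depth - 1))))))
        )
    level_sizes.append(n_species)
    # monotone non-decreasing so every internal node can get a child
    for k in range(1, len(level_sizes)):
        level_sizes[k] = max(level_sizes[k], level_sizes[k - 1])

    n_inter = depth - 3  # depths 2 .. depth-2
    idx = np.linspace(0, len(_INTERMEDIATE_RANKS) - 1, max(n_inter, 1)).round().astype(int)
    ranks_by_depth = (
        ["no rank"]
        + [_INTERMEDIATE_RANKS[i] for i in idx][:n_inter]
        + ["genus", "species"]
    )

    nodes: dict[int, TaxonNode] = {}
    next_id = 1
    levels: list[list[int]] = []
    for d, size in enumerate(level_sizes, start=1):
        ids = list(range(next_id, next_id + size))
        next_id += size
        if d == 1:
            parents = [ids[0]]
        else:
            prev = levels[-1]
            # cover every parent first, then assign the rest at random
            parents = list(prev)
            parents += [int(p) for p in rng.choice(prev, size=size - len(prev))]
            if size > len(prev):
                parents = [int(p) for p in rng.permutation(parents)]
        for tax_id, parent in zip(ids, parents):
            rank = ranks_by_depth[d - 1]
            nodes[tax_id] = TaxonNode(
                tax_id=tax_id,
                parent_id=parent if d > 1 else tax_id,
                rank=rank,
                name=f"{rank} taxon {tax_id}".strip(),
            )
        levels.append(ids)
    tree = TaxonomyTree(nodes=nodes, root_id=levels[0][0])
    return tree, levels[-1]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def simulate_genomes(
    species: Sequence[int],
    seed: int,
    genome_length: int = 20_000,
    host_length: int = 50_000,
) -> tuple[str, dict[int, str]]:
    """I.i.d. uniform-ACGT genomes: one host plus one per species taxid."""
    if genome_length <= 0 or host_length <= 0:
        raise ValueError("genome lengths must be positive")
    rng = np.random.default_rng(seed)
    host = _random_sequence(rng, host_length)
    genomes = {int(t): _random_sequence(rng, genome_length) for t in species}
    return host, genomes


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_library(
    spec: LibrarySpec,
    host_genome: str,
    genomes: Mapping[int, str],
    seed: int,
    read_length: int = 36,
    paired: bool = False,
    fragment_length: int = 300,
    error_rate: float = 0.001,
) -> tuple[list[ReadRecord], SimulationTruth]:
    """Draw a library under the mass-competition model.

    Each fragment's origin is drawn independently (species s with
    probability c_s/(m+Σc_s), host otherwise); start positions are uniform;
    substitution errors are applied i.i.d. per base.  Paired libraries emit
    two mates per fragment (forward start and reverse-complemented end of a
    ``fragment_length`` template) sharing a read id.  Qualities are constant
    Q37.  Returns the reads and a truth table covering every read.
    """
    if spec.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    masses = [spec.input_mass] + [float(spec.contaminant_masses.get(t, 0.0)) for t in genomes]
    total_mass = sum(masses)
    if total_mass <= 0:
        raise ValueError(f"library {spec.name}: no DNA mass to sequence")
    sources = [HOST_ORIGIN] + [int(t) for t in genomes]
    seqs = {HOST_ORIGIN: host_genome, **{int(t): g for t, g in genomes.items()}}
    probs = np.array(masses) / total_mass

    rng = np.random.default_rng(seed)
    origin_idx = rng.choice(len(sources), size=spec.n_reads, p=probs)
    span = fragment_length if paired else read_length
    reads: list[ReadRecord] = []
    origins: dict[str, int] = {}
    realized: dict[int, int] = {}
    qual = "F" * read_length  # Phred+33 Q37
    for i, oi in enumerate(origin_idx):
        origin = sources[oi]
        g = seqs[origin]
        if len(g) < span:
            raise ValueError(f"origin genome shorter than fragment span {span}")
        start = int(rng.integers(0, len(g) - span + 1))
        rid = f"{spec.name}:{i:07d}"
        origins[rid] = origin
        realized[origin] = realized.get(origin, 0) + 1
        frag = g[start : start + span]
        if paired:
            r1 = _apply_errors(rng, frag[:read_length], error_rate)
            r2 = _apply_errors(rng, revcomp(frag[-read_length:]), error_rate)
            reads.append(ReadRecord(rid, r1, qual, mate=1, library_id=spec.name))
            reads.append(ReadRecord(rid, r2, qual, mate=2, library_id=spec.name))
        else:
            reads.append(
                ReadRecord(
                    rid,
                    _apply_errors(rng, frag, error_rate),
                    qual,
                    mate="unpaired",
                    library_id=spec.name,
                )
            )
    truth = SimulationTruth(
        origins=origins,
        realized_counts=realized,
        expected_contaminant_fraction=spec.expected_contaminant_fraction,
    )
    return reads, truth


def simulate_dilution_series(
    masses: Sequence[float] = (1e6, 1e3, 1e2, 10.0),
    contaminant_mass: float = 0.02,
    n_pairs: int = 100_000,
    seed: int = 0,
    contaminant_taxid: int = 9606,
    read_length: int = 50,
    fragment_length: int = 300,
    host_length: int = 50_000,
    contaminant_length: int = 50_000,
    error_rate: float = 0.0,
) -> tuple[list[tuple[LibrarySpec, list[ReadRecord], SimulationTruth]], str, str]:
    """Paired-end dilution series under a constant contaminant mass.

    One library per input mass; the expected contaminant pair fraction is
    c/(c+m), so on the natural-log mass scale the binomial-GLM slope is −1.
    The default contaminant mass (0.02 pg) places the series in the regime
    where the highest-concentration library yields only a handful of
    contaminant pairs while the most dilute yields a few parts per thousand.
    The series isolates the dilution mechanism, so its default error rate is
    zero; pass ``error_rate`` to add substitution noise.

    Returns (libraries, host_genome, contaminant_genome) where each library
    entry is (spec, reads, truth).
    """
    if len(set(masses)) != len(masses) or any(m <= 0 for m in masses):
        raise ValueError("masses must be distinct and positive")
    rng = np.random.default_rng(seed)
    genome_seed, *lib_seeds = rng.integers(0, 2**31 - 1, size=1 + len(masses))
    host, genomes = simulate_genomes(
        [contaminant_taxid],
        seed=int(genome_seed),
        genome_length=contaminant_length,
        host_length=host_length,
    )
    out = []
    for m, s in zip(masses, lib_seeds):
        spec = LibrarySpec(
            name=f"mass{m:g}pg",
            input_mass=float(m),
            contaminant_masses={contaminant_taxid: contaminant_mass},
            n_reads=n_pairs,
        )
        reads, truth = simulate_library(
            spec,
            host,
            genomes,
            seed=int(s),
            read_length=read_length,
            paired=True,
            fragment_length=fragment_length,
            error_rate=error_rate,
        )
        out.append((spec, reads, truth))
    return out, host, genomes[contaminant_taxid]


def simulate_genus_profile_pair(
    seed: int,
    n_genera: int = 40,
    alpha: float = 0.3,
    n_positive: int = 50_000,
    n_blank: int = 500,
    matched: bool = True,
) -> tuple[dict[int, int], dict[int, int]]:
    """Genus count profiles for a pooled positive and a pooled blank library.

    Both pools draw multinomially from Dirichlet(alpha) genus proportions;
    ``matched=True`` shares one proportion vector (same experiment, same
    contaminant spectrum), ``matched=False`` draws independent vectors
    (different experiments).  The sparse concentration (alpha < 1) mimics
    contaminant spectra dominated by a few genera with a long low-frequency
    tail; the blank's small total reflects the low yield of true blanks.
    Genus keys are 1-based ids; zero-count genera are omitted.
    """
    rng = np.random.default_rng(seed)
    p_pos = rng.dirichlet(np.full(n_genera, alpha))
    p_blank = p_pos if matched else rng.dirichlet(np.full(n_genera, alpha))
    pos = rng.multinomial(n_positive, p_pos)
    blank = rng.multinomial(n_blank, p_blank)
    return (
        {g + 1: int(c) for g, c in enumerate(pos) if c > 0},
        {g + 1: int(c) for g, c in enumerate(blank) if c > 0},
    )
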