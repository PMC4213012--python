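"""Targeted-genome screening of host-unmapped reads with evenness filtering.

Host-screened reads are mapped strictly (no seed mismatches) against a small
panel of target genomes (e.g. chloroplasts).  Two confounders are filtered:

* reads better explained by sequences outside the panel are removed by
  cross-checking each matching read against a broader labelled database
  (:func:`crosscheck_broader`);
* panel genomes whose matches pile onto a single locus — the signature of a
  low-complexity or repetitive artifact rather than genuine genome-wide
  presence — are flagged by a windowed coverage-concentration statistic
  (:func:`coverage_evenness`).

Surviving per-genome counts are reported as reads per million of the pooled
input (:func:`per_million_frequencies`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alignment import (
    AlignmentHit,
    ExactMatchIndex,
    GenomeIndex,
    ReadRecord,
    map_reads,
    perfect_matches,
)

__all__ = [
    "CoverageProfile",
    "EvennessReport",
    "screen_targets",
    "crosscheck_broader",
    "coverage_evenness",
    "per_million_frequencies",
]


@dataclass
class CoverageProfile:
    genome_id: str
    depth: np.ndarray  # per-position aligned-base depth

    @classmethod
    def from_hits(cls, genome_id: str, hits: Sequence[AlignmentHit], genome_length: int):
        depth = np.zeros(genome_length, dtype=np.int64)
        for h in hits:
            depth[h.start : h.start + h.length] += 1
        return cls(genome_id=genome_id, depth=depth)


@dataclass(frozen=True)
class EvennessReport:
    genome_id: str
    window: int
    max_window_fraction: float
    passed: bool
    uninformative: bool = False


def screen_targets(
    unmapped_reads: Sequence[ReadRecord],
    panel_index: GenomeIndex,
    max_seed_mismatches: int = 0,
    max_other_mismatches: int = 2,
) -> tuple[dict[str, list[AlignmentHit]], dict[str, int]]:
    """Strictly map host-unmapped reads against a panel of target genomes.

    Returns per-genome hit lists and per-genome distinct-read counts; a read
    may hit multiple genomes (and contributes to each), but is counted once
    per genome however many loci it hits there.
    """
    if len(panel_index.names) == 0:
        raise ValueError("empty target panel")
    hits_by_genome: dict[str, list[AlignmentHit]] = {n: [] for n in panel_index.names}
    counted: dict[str, set] = {n: set() for n in panel_index.names}
    all_hits = map_reads(
        panel_index, unmapped_reads, max_seed_mismatches, max_other_mismatches
    )
    for read, read_hits in zip(unmapped_reads, all_hits):
        for h in read_hits:
            hits_by_genome[h.reference_name].append(h)
            counted[h.reference_name].add((read.read_id, read.mate))
    counts = {n: len(counted[n]) for n in panel_index.names}
    return hits_by_genome, counts


def crosscheck_broader(
    reads: Sequence[ReadRecord],
    hits_by_genome: Mapping[str, Sequence[AlignmentHit]],
    broad_index: ExactMatchIndex,
    target_labels: Mapping[str, bool],
    panel_to_broad: Mapping[str, str] | None = None,
    min_anchor: int | None = None,
) -> dict[str, list[AlignmentHit]]:
    """Remove target hits for reads better explained outside the target set.

    ``target_labels`` marks each broad-database sequence as target (True) or
    non-target (False).  A read's hits to a panel genome are removed iff its
    longest exact match to any non-target sequence is at least as long as its
    longest exact match to that genome's broad-database counterpart (ties
    remove — conservative).  ``panel_to_broad`` maps panel genome ids to
    broad-database ids when they differ.
    """
    reads_by_key = {(r.read_id, r.mate): r for r in reads}
    L = min_anchor if min_anchor is not None else broad_index.word_size
    match_cache: dict[tuple, dict[str, int]] = {}

    def longest_by_subject(read: ReadRecord) -> dict[str, int]:
        key = (read.read_id, read.mate)
        if key not in match_cache:
            best: dict[str, int] = {}
            if len(read.sequence) >= L:
                for h in perfect_matches(broad_index, read, L):
                    best[h.subject_id] = max(best.get(h.subject_id, 0), h.match_length)
            match_cache[key] = best
        return match_cache[key]

    filtered: dict[str, list[AlignmentHit]] = {}
    for genome, hits in hits_by_genome.items():
        broad_id = (panel_to_broad or {}).get(genome, genome)
        kept: list[AlignmentHit] = []
        for h in hits:
            read = reads_by_key.get((h.read_id, 1)) or reads_by_key.get(
                (h.read_id, "unpaired")
            ) or reads_by_key.get((h.read_id, 2))
            # prefer the exact mate the hit came from when resolvable
            for mate in (1, 2, "unpaired"):
                cand = reads_by_key.get((h.read_id, mate))
                if cand is not None and len(cand.sequence) == h.length:
                    read = cand
                    break
            if read is None:
                kept.append(h)
                continue
            best = longest_by_subject(read)
            target_len = best.get(broad_id, 0)
            nontarget_len = max(
                (l for s, l in best.items() if not target_labels.get(s, False)),
                default=0,
            )
            if nontarget_len == 0 or nontarget_len < target_len:
                kept.append(h)
        filtered[genome] = kept
    return filtered


def coverage_evenness(
    hits: Sequence[AlignmentHit],
    genome_id: str,
    genome_length: int,
    window: int = 1000,
    threshold: float = 0.5,
) -> EvennessReport:
    """Windowed coverage-concentration test for a target genome.

    ``max_window_fraction`` is the share of all aligned bases falling in the
    single most-covered window of ``window`` bp; a genome passes iff that
    share is at most ``threshold``.  Genomes with no hits pass trivially and
    are flagged uninformative.
    """
    if genome_length < window:
        raise ValueError("genome shorter than the evenness window")
    if not hits:
        return EvennessReport(genome_id, window, 0.0, True, uninformative=True)
    profile = CoverageProfile.from_hits(genome_id, hits, genome_length)
    total = int(profile.depth.sum())
    csum = np.concatenate([[0], np.cumsum(profile.depth)])
    window_sums = csum[window:] - csum[:-window]
    frac = float(window_sums.max() / total)
    return EvennessReport(genome_id, window, frac, frac <= threshold)


def per_million_frequencies(
    counts: Mapping[str, int], pooled_total: int
) -> dict[str, float]:
    """Per-genome read frequency per million pooled reads."""
    if pooled_total <= 0:
        raise ValueError("pooled_total must be positive")
    return {g: c * 1e6 / pooled_total for g, c in counts.items()}
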