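"""Seeded ungapped read alignment and exact-substring database search.

Two search engines back the pipeline:

* :class:`GenomeIndex` / :func:`map_read` — a bowtie-1-style ungapped aligner:
  the first ``seed_length`` bases of a read (the seed) may mismatch the
  reference at most ``max_seed_mismatches`` times, the remainder at most
  ``max_other_mismatches`` times.  Candidate loci are found by a pigeonhole
  word index (any seed alignment with <= n mismatches shares an exact w-mer
  with the reference when the seed is split into more than n disjoint
  w-words), then verified with vectorized Hamming comparison.  Used for host
  screening (permissive, n = 3) and targeted-genome screening (strict, n = 0).

* :class:`ExactMatchIndex` / :func:`perfect_matches` — reports every database
  sequence sharing with a read a contiguous, N-free, character-identical
  substring of at least ``L`` bases ("perfect match").  Anchored on shared
  16-mers with bidirectional extension; lossless for L >= word size because
  any qualifying match contains a shared word.

``N`` bases never participate in seeds, anchors or extensions and count as a
mismatch against everything.  Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ReadRecord",
    "AlignmentHit",
    "PerfectHit",
    "GenomeIndex",
    "ExactMatchIndex",
    "map_read",
    "map_reads",
    "screen_host",
    "paired_alt_fraction",
    "build_exact_index",
    "perfect_matches",
    "revcomp",
]

# Base codes.  Reads: ACGT -> 0..3, anything else -> 4.  References: ACGT ->
# 0..3, anything else -> 5, inter-reference padding -> 6.  Distinct non-ACGT
# codes on the two sides make N-vs-N a mismatch by construction.
_READ_CODE = np.full(256, 4, dtype=np.uint8)
_REF_CODE = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _READ_CODE[ord(_b)] = _i
    _READ_CODE[ord(_b.lower())] = _i
    _REF_CODE[ord(_b)] = _i
    _REF_CODE[ord(_b.lower())] = _i

_PAD_CODE = 6
_PAD_LEN = 512  # longer than any supported read

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMP)[::-1]


def _encode(seq: str, table: np.ndarray) -> np.ndarray:
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read; ``mate`` is 1, 2 or ``"unpaired"``."""

    read_id: str
    sequence: str
    quality: str | None = None
    mate: int | str = "unpaired"
    library_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.read_id}: quality/sequence length mismatch")


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    reference_name: str
    start: int  # 0-based leftmost reference coordinate
    strand: str  # "+" or "-"
    seed_mismatches: int
    total_mismatches: int
    length: int  # aligned (= read) length


@dataclass(frozen=True)
class PerfectHit:
    """An exact, full-identity match of >= L bases between read and subject."""

    read_id: str
    subject_id: str
    subject_taxid: int | None
    match_length: int
    strand: str
    subject_offset: int  # 0-based on the subject's forward strand


class GenomeIndex:
    """Word index over one or more reference sequences for seeded alignment.

    Parameters
    ----------
    references
        Mapping of reference name to sequence string (or iterable of pairs).
    seed_length
        Length of the read prefix treated as the seed (bowtie -n mode
        default: 28).
    word_size
        Indexed word length; the seed is split into ``seed_length //
        word_size`` disjoint words, so alignments with up to
        ``seed_length // word_size - 1`` seed mismatches are found losslessly.
    """

    def __init__(
        self,
        references: Mapping[str, str] | Iterable[tuple[str, str]],
        seed_length: int = 28,
        word_size: int = 7,
    ):
        items = list(references.items()) if hasattr(references, "items") else list(references)
        if not items:
            raise ValueError("empty reference set")
        if seed_length < word_size:
            raise ValueError("seed_length must be >= word_size")
        self.seed_length = seed_length
        self.word_size = word_size
        self.names = [name for name, _ in items]
        self.lengths = np.array([len(seq) for _, seq in items], dtype=np.int64)
        if (self.lengths < 1).any():
            raise ValueError("empty reference sequence")

        # Concatenate references with mismatch-everything padding between and
        # around them so window gathers never cross sequences meaningfully.
        parts: list[np.ndarray] = []
        starts: list[int] = []
        pos = 0
        pad = np.full(_PAD_LEN, _PAD_CODE, dtype=np.uint8)
        for _, seq in items:
            parts.append(pad)
            pos += _PAD_LEN
            starts.append(pos)
            parts.append(_encode(seq, _REF_CODE))
            pos += len(seq)
        parts.append(pad)
        self._concat = np.concatenate(parts)
        self.starts = np.array(starts, dtype=np.int64)

        # CSR word -> positions table over the forward concatenated genome.
        w = word_size
        codes = self._concat.astype(np.int64)
        if len(codes) >= w:
            win = np.lib.stride_tricks.sliding_window_view(codes, w)
            valid = (win < 4).all(axis=1)
            powers = 4 ** np.arange(w - 1, -1, -1, dtype=np.int64)
            words = win @ powers
            positions = np.nonzero(valid)[0]
            words = words[valid]
            order = np.argsort(words, kind="stable")
            self._word_keys, split = np.unique(words[order], return_index=True)
            self._row_ptr = np.concatenate([split, [len(words)]]).astype(np.int64)
            self._pos_flat = positions[order]
        else:  # degenerate tiny reference
            self._word_keys = np.empty(0, dtype=np.int64)
            self._row_ptr = np.zeros(1, dtype=np.int64)
            self._pos_flat = np.empty(0, dtype=np.int64)

    # -- internal batch machinery -------------------------------------------

    def _lookup(self, words: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (query_index, genome_position) pairs for matching words."""
        j = np.searchsorted(self._word_keys, words)
        j_clipped = np.minimum(j, max(len(self._word_keys) - 1, 0))
        found = valid & (len(self._word_keys) > 0)
        if len(self._word_keys):
            found = found & (self._word_keys[j_clipped] == words)
        counts = np.where(found, self._row_ptr[j_clipped + 1] - self._row_ptr[j_clipped], 0)
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qidx = np.repeat(np.arange(len(words)), counts)
        starts = self._row_ptr[j_clipped]
        # multi-range gather: for each query, its slice of _pos_flat
        cum = np.cumsum(counts)
        offset = np.repeat(starts - (cum - counts), counts)
        flat_idx = offset + np.arange(total)
        return qidx, self._pos_flat[flat_idx]

    def _map_matrix(
        self,
        mat: np.ndarray,
        n_seed: int,
        n_other: int,
        chunk: int = 1_000_000,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Map equal-length read matrix (n_reads x R, read codes).

        Returns accepted hit arrays (read_idx, ref_idx, local_start,
        strand_is_rev, seed_mm, total_mm) — the last two merged into one
        return tuple of five arrays with mismatch counts stacked.
        """
        n_reads, R = mat.shape
        seed = self.seed_length
        if R < seed:
            raise ValueError(f"read length {R} shorter than seed length {seed}")
        npieces = seed // self.word_size
        if n_seed >= npieces:
            raise ValueError(
                f"max_seed_mismatches={n_seed} requires seed_length//word_size "
                f"> {n_seed} disjoint words (have {npieces})"
            )
        rc = np.where(mat < 4, 3 - mat, mat)[:, ::-1]
        powers = 4 ** np.arange(self.word_size - 1, -1, -1, dtype=np.int64)

        out: list[tuple] = []
        for strand, Q in (("+", mat), ("-", rc)):
            seed_cols = (
                np.arange(0, seed) if strand == "+" else np.arange(R - seed, R)
            )
            piece_offsets = (
                [i * self.word_size for i in range(npieces)]
                if strand == "+"
                else [R - seed + i * self.word_size for i in range(npieces)]
            )
            cand_read: list[np.ndarray] = []
            cand_start: list[np.ndarray] = []
            for o in piece_offsets:
                piece = Q[:, o : o + self.word_size].astype(np.int64)
                valid = (piece < 4).all(axis=1)
                words = piece @ powers
                qidx, gpos = self._lookup(words, valid)
                cand_read.append(qidx)
                cand_start.append(gpos - o)
            read_idx = np.concatenate(cand_read)
            gstart = np.concatenate(cand_start)
            if len(read_idx) == 0:
                continue
            # restrict to alignments fully inside one reference
            ref_idx = np.searchsorted(self.starts, gstart, side="right") - 1
            ref_idx = np.clip(ref_idx, 0, len(self.starts) - 1)
            ok = (gstart >= self.starts[ref_idx]) & (
                gstart + R <= self.starts[ref_idx] + self.lengths[ref_idx]
            )
            read_idx, gstart, ref_idx = read_idx[ok], gstart[ok], ref_idx[ok]
            if len(read_idx) == 0:
                continue
            # dedupe (read, start)
            key = read_idx * np.int64(len(self._concat)) + gstart
            _, uniq = np.unique(key, return_index=True)
            read_idx, gstart, ref_idx = read_idx[uniq], gstart[uniq], ref_idx[uniq]

            for lo in range(0, len(read_idx), max(1, chunk // max(R, 1))):
                hi = lo + max(1, chunk // max(R, 1))
                ri, gs, fi = read_idx[lo:hi], gstart[lo:hi], ref_idx[lo:hi]
                windows = self._concat[gs[:, None] + np.arange(R)]
                mm = windows != Q[ri]
                total_mm = mm.sum(axis=1)
                seed_mm = mm[:, seed_cols].sum(axis=1)
                accept = (seed_mm <= n_seed) & (total_mm - seed_mm <= n_other)
                if accept.any():
                    out.append(
                        (
                            ri[accept],
                            fi[accept],
                            gs[accept] - self.starts[fi[accept]],
                            np.full(int(accept.sum()), strand == "-"),
                            seed_mm[accept],
                            total_mm[accept],
                        )
                    )
        if not out:
            e = np.empty(0, dtype=np.int64)
            return e, e, e, np.empty(0, dtype=bool), np.empty((0, 2), dtype=np.int64)
        read_idx = np.concatenate([t[0] for t in out])
        ref_idx = np.concatenate([t[1] for t in out])
        local = np.concatenate([t[2] for t in out])
        is_rev = np.concatenate([t[3] for t in out])
        mms = np.stack(
            [np.concatenate([t[4] for t in out]), np.concatenate([t[5] for t in out])],
            axis=1,
        )
        return read_idx, ref_idx, local, is_rev, mms


def map_reads(
    index: GenomeIndex,
    reads: Sequence[ReadRecord],
    max_seed_mismatches: int,
    max_other_mismatches: int = 2,
) -> list[list[AlignmentHit]]:
    """Map a batch of reads; returns one (possibly empty) hit list per read.

    Reads are grouped by length internally and verified with vectorized
    Hamming comparison against pigeonhole candidates.
    """
    hits: list[list[AlignmentHit]] = [[] for _ in reads]
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r.sequence), []).append(i)
    for R, idxs in by_len.items():
        mat = np.empty((len(idxs), R), dtype=np.uint8)
        for row, i in enumerate(idxs):
            mat[row] = _encode(reads[i].sequence, _READ_CODE)
        ridx, fidx, local, is_rev, mms = index._map_matrix(
            mat, max_seed_mismatches, max_other_mismatches
        )
        for k in range(len(ridx)):
            i = idxs[int(ridx[k])]
            hits[i].append(
                AlignmentHit(
                    read_id=reads[i].read_id,
                    reference_name=index.names[int(fidx[k])],
                    start=int(local[k]),
                    strand="-" if is_rev[k] else "+",
                    seed_mismatches=int(mms[k, 0]),
                    total_mismatches=int(mms[k, 1]),
                    length=R,
                )
            )
    for h in hits:
        h.sort(key=lambda x: (x.reference_name, x.start, x.strand))
    return hits


def map_read(
    index: GenomeIndex,
    read: ReadRecord,
    max_seed_mismatches: int,
    max_other_mismatches: int = 2,
) -> list[AlignmentHit]:
    """All ungapped placements of one read meeting the mismatch limits."""
    return map_reads(index, [read], max_seed_mismatches, max_other_mismatches)[0]


def _mapped_mask(
    index: GenomeIndex,
    reads: Sequence[ReadRecord],
    max_seed_mismatches: int,
    max_other_mismatches: int,
    batch: int = 50_000,
) -> np.ndarray:
    """Boolean mask: does each read have >= 1 accepted placement?"""
    mask = np.zeros(len(reads), dtype=bool)
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r.sequence), []).append(i)
    for R, idxs in by_len.items():
        for lo in range(0, len(idxs), batch):
            sub = idxs[lo : lo + batch]
            mat = np.empty((len(sub), R), dtype=np.uint8)
            for row, i in enumerate(sub):
                mat[row] = _encode(reads[i].sequence, _READ_CODE)
            ridx, *_ = index._map_matrix(mat, max_seed_mismatches, max_other_mismatches)
            for k in np.unique(ridx):
                mask[sub[int(k)]] = True
    return mask


def screen_host(
    library: Sequence[ReadRecord],
    host_index: GenomeIndex,
    max_seed_mismatches: int = 3,
    max_other_mismatches: int = 2,
) -> tuple[set[str], list[ReadRecord]]:
    """Partition a library into host-mapped read ids and unmapped reads.

    A read is "mapped" iff it has at least one placement under the permissive
    seed policy.  Unmapped reads retain input order and pairing metadata.
    Returns ``(mapped_keys, unmapped_reads)`` where mapped_keys are
    ``(read_id, mate)`` tuples (read ids are shared between mates).
    """
    if not library:
        return set(), []
    mask = _mapped_mask(host_index, library, max_seed_mismatches, max_other_mismatches)
    mapped = {(r.read_id, r.mate) for r, m in zip(library, mask) if m}
    unmapped = [r for r, m in zip(library, mask) if not m]
    return mapped, unmapped


def paired_alt_fraction(
    pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    primary_index: GenomeIndex,
    alt_index: GenomeIndex,
    pair_window: int = 1000,
    primary_seed_mismatches: int = 3,
    alt_seed_mismatches: int = 0,
    max_other_mismatches: int = 2,
) -> tuple[int, int, float]:
    """Fraction of read pairs that preferentially map to an alternate genome.

    A pair is a hit iff both ends fail the permissive primary screen, both
    ends map to the alternate genome under the strict seed policy, and some
    pair of their placements lies on the same reference with
    ``|start1 - start2| <= pair_window``.  Orientation and mate order are
    ignored.  Returns (hit_pair_count, total_pair_count, fraction).
    """
    for a, b in pairs:
        if a.mate == "unpaired" or b.mate == "unpaired":
            raise ValueError("paired_alt_fraction requires paired reads")
    total = len(pairs)
    if total == 0:
        return 0, 0, 0.0
    flat = [r for pair in pairs for r in pair]
    mapped = _mapped_mask(
        primary_index, flat, primary_seed_mismatches, max_other_mismatches
    )
    surviving = [
        i for i in range(total) if not mapped[2 * i] and not mapped[2 * i + 1]
    ]
    if not surviving:
        return 0, total, 0.0
    ends = [r for i in surviving for r in pairs[i]]
    alt_hits = map_reads(alt_index, ends, alt_seed_mismatches, max_other_mismatches)
    hit_pairs = 0
    for k, i in enumerate(surviving):
        h1, h2 = alt_hits[2 * k], alt_hits[2 * k + 1]
        if not h1 or not h2:
            continue
        found = False
        for a in h1:
            for b in h2:
                if a.reference_name == b.reference_name and abs(a.start - b.start) <= pair_window:
                    found = True
                    break
            if found:
                break
        hit_pairs += found
    return hit_pairs, total, hit_pairs / total


# ---------------------------------------------------------------------------
# Exact-substring ("perfect match") database engine
# ---------------------------------------------------------------------------


class ExactMatchIndex:
    """Anchor-word index over a sequence database for perfect-match queries."""

    def __init__(
        self,
        records: Mapping[str, str] | Iterable[tuple[str, str]],
        taxid_map: Mapping[str, int] | None = None,
        word_size: int = 16,
    ):
        items = list(records.items()) if hasattr(records, "items") else list(records)
        ids = [name for name, _ in items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in database: {dupes}")
        self.word_size = word_size
        self.ids = ids
        self.taxids = [
            (taxid_map or {}).get(name) for name in ids
        ]
        self._seqs = [_encode(seq, _REF_CODE) for _, seq in items]
        self._words: dict[int, list[tuple[int, int]]] = {}
        powers = 4 ** np.arange(word_size - 1, -1, -1, dtype=np.int64)
        for si, codes in enumerate(self._seqs):
            if len(codes) < word_size:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), word_size)
            valid = (win < 4).all(axis=1)
            words = win @ powers
            for p in np.nonzero(valid)[0]:
                self._words.setdefault(int(words[p]), []).append((si, int(p)))

    def __len__(self) -> int:
        return len(self.ids)


def build_exact_index(
    records: Mapping[str, str] | Iterable[tuple[str, str]],
    taxid_map: Mapping[str, int] | None = None,
    min_match: int = 40,
    word_size: int = 16,
) -> ExactMatchIndex:
    """Build an exact-match index; ``min_match`` must be >= the anchor word size."""
    if min_match < word_size:
        raise ValueError(
            f"min_match ({min_match}) must be >= anchor word size ({word_size})"
        )
    return ExactMatchIndex(records, taxid_map=taxid_map, word_size=word_size)


def perfect_matches(
    index: ExactMatchIndex,
    read: ReadRecord,
    L: int,
    max_subjects: int | None = None,
) -> list[PerfectHit]:
    """Every database sequence sharing an exact N-free substring of >= L bases.

    At most one hit per (subject, strand) is reported, keeping the longest.
    ``max_subjects`` optionally caps the number of subjects reported (longest
    matches first), mirroring aligner report caps; by default all subjects
    are reported.
    """
    if len(read.sequence) < L:
        raise ValueError(
            f"read {read.read_id} shorter ({len(read.sequence)}) than L={L}"
        )
    if L < index.word_size:
        raise ValueError(f"L={L} below anchor word size {index.word_size}")
    w = index.word_size
    powers = 4 ** np.arange(w - 1, -1, -1, dtype=np.int64)
    best: dict[tuple[int, str], tuple[int, int]] = {}  # (subject, strand) -> (len, offset)
    for strand, qseq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        q = _encode(qseq, _READ_CODE)
        n = len(q)
        if n < w:
            continue
        win = np.lib.stride_tricks.sliding_window_view(q.astype(np.int64), w)
        valid = (win < 4).all(axis=1)
        words = win @ powers
        covered: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for i in np.nonzero(valid)[0]:
            entries = index._words.get(int(words[i]))
            if not entries:
                continue
            for si, p in entries:
                diag = p - int(i)
                done = covered.get((si, diag))
                if done and any(s <= i < e for s, e in done):
                    continue
                subj = index._seqs[si]
                # bidirectional exact extension; non-ACGT codes never extend
                qi, pj = int(i), p
                while qi > 0 and pj > 0 and q[qi - 1] == subj[pj - 1] and q[qi - 1] < 4:
                    qi -= 1
                    pj -= 1
                qe, pe = int(i) + w, p + w
                while qe < n and pe < len(subj) and q[qe] == subj[pe] and q[qe] < 4:
                    qe += 1
                    pe += 1
                covered.setdefault((si, diag), []).append((qi, qe))
                length = qe - qi
                if length >= L:
                    key = (si, strand)
                    if key not in best or length > best[key][0]:
                        best[key] = (length, pj)
    hits = [
        PerfectHit(
            read_id=read.read_id,
            subject_id=index.ids[si],
            subject_taxid=index.taxids[si],
            match_length=length,
            strand=strand,
            subject_offset=offset,
        )
        for (si, strand), (length, offset) in best.items()
    ]
    hits.sort(key=lambda h: (-h.match_length, h.subject_id, h.strand))
    if max_subjects is not None:
        keep: list[PerfectHit] = []
        subjects: set[str] = set()
        for h in hits:
            if h.subject_id in subjects or len(subjects) < max_subjects:
                subjects.add(h.subject_id)
                keep.append(h)
        hits = keep
    return hits
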