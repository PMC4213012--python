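"""Readers and writers for the pipeline's file formats.

FASTA/FASTQ go through Biopython; tables (taxid maps, manifests, count
matrices, reports) are plain TSV via pandas.  Coordinates in human-readable
outputs are 1-based fully-closed; everything in memory is 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import AlignmentHit, PerfectHit, ReadRecord
from .classification import AssignmentOutcome
from .statistics import ConcordanceResult, DilutionFit
from .targeted_screen import CoverageProfile, EvennessReport

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_taxid_map",
    "write_taxid_map",
    "read_manifest",
    "write_assignments",
    "write_perfect_hits",
    "write_dilution_fit",
    "write_concordance",
    "write_coverage_bedgraph",
    "write_evenness",
    "write_accounting",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fastq(
    path: str | Path, library_id: str = "", mate: int | str = "unpaired"
) -> list[ReadRecord]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(
            ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                quality=qual,
                mate=mate,
                library_id=library_id,
            )
        )
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_taxid_map(path: str | Path) -> dict[str, int]:
    """2-column TSV (sequence id, taxid) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["seq_id", "taxid"], dtype=str)
    return {row.seq_id: int(row.taxid) for row in df.itertuples()}


def write_taxid_map(mapping: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, taxid in mapping.items():
            fh.write(f"{seq_id}\t{taxid}\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Library manifest TSV: sample, fastq (comma-separated for pairs),
    role (positive|blank), mass_pg (optional)."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns or "fastq" not in df.columns:
        raise ValueError("manifest must have 'sample' and 'fastq' columns")
    return df


def write_assignments(
    outcomes: Mapping[str, Sequence[AssignmentOutcome]], path: str | Path
) -> None:
    rows = [
        {
            "sample": sample,
            "read_id": o.read_id,
            "status": o.status,
            "category_taxid": o.category if o.category is not None else "",
            "reason": o.reason or "",
        }
        for sample, outs in outcomes.items()
        for o in outs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_perfect_hits(hits: Iterable[PerfectHit], path: str | Path) -> None:
    rows = [
        {
            "read_id": h.read_id,
            "subject_id": h.subject_id,
            "taxid": h.subject_taxid if h.subject_taxid is not None else "",
            "length": h.match_length,
            "strand": h.strand,
            "offset": h.subject_offset + 1,  # 1-based in human-readable output
        }
        for h in hits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_dilution_fit(fit: DilutionFit, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"term": "intercept", "estimate": fit.intercept, "se": fit.se_intercept},
            {
                "term": "ln_mass",
                "estimate": fit.slope,
                "se": fit.se_slope,
                "z": fit.z,
                "p": fit.p,
                "iterations": fit.iterations,
                "converged": fit.converged,
            },
        ]
    ).to_csv(path, sep="\t", index=False)


def write_concordance(
    result: ConcordanceResult,
    positive_counts: Mapping,
    blank_counts: Mapping,
    path: str | Path,
) -> None:
    rows = [
        {
            "genus": g,
            "positive_count": positive_counts.get(g, 0),
            "blank_count": blank_counts.get(g, 0),
            "positive_log": result.positive_log[i],
            "blank_log": result.blank_log[i],
        }
        for i, g in enumerate(result.genera)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_coverage_bedgraph(profiles: Iterable[CoverageProfile], path: str | Path) -> None:
    """Run-length-encoded per-position depth in BedGraph-style TSV."""
    with open(path, "w") as fh:
        for prof in profiles:
            depth = prof.depth
            start = 0
            for i in range(1, len(depth) + 1):
                if i == len(depth) or depth[i] != depth[start]:
                    if depth[start] > 0:
                        fh.write(f"{prof.genome_id}\t{start}\t{i}\t{int(depth[start])}\n")
                    start = i


def write_evenness(reports: Iterable[EvennessReport], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "genome": r.genome_id,
                "window": r.window,
                "max_window_fraction": r.max_window_fraction,
                "pass": r.passed,
                "uninformative": r.uninformative,
            }
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False)


def write_accounting(stage_counts: Mapping[str, Mapping[str, int]], path: str | Path) -> None:
    """Per-sample per-stage read counts (machine-readable conservation check)."""
    rows = [
        {"sample": sample, **{k: int(v) for k, v in stages.items()}}
        for sample, stages in stage_counts.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
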