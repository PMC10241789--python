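"""Readers and writers for the on-disk formats the pipeline consumes.

Formats: BED3/BED6 intervals, a tab-delimited promoter-capture interaction
table (ibed-like), JASPAR PFM text, FASTA sequences, TSV count/expression
matrices with a header, and bedGraph tracks.  All coordinates on disk are
0-based half-open, matching the in-memory convention.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from crestreg.intervals import GeneAnnotation, GenomicInterval
from crestreg.motifs import MotifPFM


class ParseError(ValueError):
    """A malformed input line; the message names the file and line number."""


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (0-based half-open), preserving order."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | Path,
              names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Interaction tables (ibed-like)


@dataclass(frozen=True)
class InteractionRecord:
    """One bait-fragment <-> other-end link from promoter-capture data.

    ``score`` is a CHiCAGO-like interaction significance score; >=5 is the
    conventional high-confidence threshold.  ``n_reads`` is the raw
    supporting read count N.
    """

    bait: GenomicInterval
    bait_gene: str
    other_end: GenomicInterval
    n_reads: int
    score: float

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if self.bait == self.other_end:
            raise ValueError("bait and other_end must be distinct fragments")


_INTERACTION_COLUMNS = [
    "bait_chrom", "bait_start", "bait_end", "bait_gene",
    "oe_chrom", "oe_start", "oe_end", "n_reads", "score",
]


def read_interaction_table(path: str | Path) -> list[InteractionRecord]:
    """Read a tab-delimited interaction table with the canonical header."""
    records: list[InteractionRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _INTERACTION_COLUMNS:
            raise ParseError(
                f"{path}:1: header must be {_INTERACTION_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            try:
                record = InteractionRecord(
                    bait=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    bait_gene=f[3],
                    other_end=GenomicInterval(f[4], int(f[5]), int(f[6])),
                    n_reads=int(f[7]),
                    score=float(f[8]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(record)
    return records


def write_interaction_table(records: list[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_INTERACTION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.bait.chrom}\t{r.bait.start}\t{r.bait.end}\t{r.bait_gene}\t"
                f"{r.other_end.chrom}\t{r.other_end.start}\t{r.other_end.end}\t"
                f"{r.n_reads}\t{r.score:.6g}\n"
            )


# ---------------------------------------------------------------------------
# JASPAR PFMs (via Bio.motifs)


def read_jaspar_pfm(path: str | Path) -> list[MotifPFM]:
    """Read motifs in JASPAR text format; counts row order A, C, G, T."""
    with open(path) as fh:
        text = fh.read()
    try:
        parsed = bio_motifs.parse(_stdio.StringIO(text), "jaspar")
        out = []
        for m in parsed:
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            out.append(
                MotifPFM(motif_id=m.matrix_id or m.name, counts=counts, name=m.name or "")
            )
    except Exception as exc:  # Bio.motifs raises bare Exception on bad input
        raise ParseError(f"{path}: malformed JASPAR PFM ({exc})") from exc
    if not out:
        raise ParseError(f"{path}: no motifs found")
    return out


def write_jaspar_pfm(motifs_list: list[MotifPFM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs_list:
            fh.write(f">{m.motif_id} {m.name or m.motif_id}\n")
            for row, base in zip(m.counts, "ACGT"):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {name: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene annotation TSV (minimal contract: gene_id, chrom, tss, strand, length)


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand", "gene_length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        tss = GenomicInterval(row.chrom, int(row.tss), int(row.tss) + 1, row.strand)
        genes.append(GeneAnnotation(row.gene_id, tss, int(row.gene_length_bp)))
    return genes


def write_annotation(genes: list[GeneAnnotation], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "tss": g.tss_pos,
            "strand": g.tss.strand,
            "gene_length_bp": g.gene_length_bp,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrices and tracks


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix whose first column is the row identifier."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def write_bedgraph(track: list[tuple[GenomicInterval, float]], path: str | Path) -> None:
    """Write (interval, value) pairs as bedGraph, sorted by coordinate."""
    ordered = sorted(track, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    with open(path, "w") as fh:
        for iv, value in ordered:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:.6g}\n")
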