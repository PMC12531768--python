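"""Readers, writers and core record types for every external format the
pipeline touches.

Coordinate conventions (used consistently across the package):

* interval data (BED, enhancer peaks, conserved regions, coding intervals)
  are **0-based half-open** ``[start, end)``;
* mutation positions and transcription start sites are **1-based**, as in
  VCF; a single-base mutation at position ``pos`` maps to interval space as
  ``[pos - 1, pos)``.

Chromosome names are matched as exact strings; no "chr" prefix
normalization is performed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "MutationRecord",
    "MUTATION_COLUMNS",
    "read_bed",
    "write_bed",
    "read_mutation_table",
    "write_mutation_table",
    "records_to_frame",
    "frame_to_records",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_signature_catalog",
    "write_signature_catalog",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
]


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A half-open coordinate span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValueError(f"interval score must be nonnegative, got {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A gene anchored at its transcription start site (TSS, 1-based) with
    normalized (sorted, non-overlapping) coding intervals."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    coding_intervals: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 1:
            raise ValueError(f"tss must be a 1-based coordinate >= 1, got {self.tss}")
        ivs = sorted(self.coding_intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"coding intervals of {self.gene_id} overlap after sorting"
                )
        object.__setattr__(self, "coding_intervals", tuple(ivs))

    @property
    def tss0(self) -> int:
        """TSS in 0-based coordinates."""
        return self.tss - 1


@dataclasses.dataclass(frozen=True)
class MutationRecord:
    """One somatic variant observed in one tumor sample, with read support in
    that sample and in the patient-matched normal."""

    patient_id: str
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    t_depth: int
    t_alt: int
    n_depth: int
    n_alt: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self.ref}")
        if self.t_alt > self.t_depth:
            raise ValueError(
                f"t_alt ({self.t_alt}) exceeds t_depth ({self.t_depth}) at "
                f"{self.chrom}:{self.pos}"
            )
        if self.n_alt > self.n_depth:
            raise ValueError(
                f"n_alt ({self.n_alt}) exceeds n_depth ({self.n_depth}) at "
                f"{self.chrom}:{self.pos}"
            )
        if min(self.t_depth, self.t_alt, self.n_depth, self.n_alt) < 0:
            raise ValueError("read counts must be nonnegative")
        if len(self.ref) != 1 or len(self.alt) != 1:
            # multi-allelic / indel rows must be pre-split or excluded upstream
            if "," in self.ref or "," in self.alt:
                raise ValueError(
                    f"multi-allelic row at {self.chrom}:{self.pos}; pre-split "
                    "into one row per alternate allele"
                )

    @property
    def variant_id(self) -> tuple[str, str, int, str, str]:
        """Identity of the variant within its patient."""
        return (self.patient_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


MUTATION_COLUMNS = [
    "patient_id", "sample_id", "chrom", "pos", "ref", "alt",
    "t_depth", "t_alt", "n_depth", "n_alt",
]


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-5 column BED file into intervals, preserving file order.

    Column 4 (if present) is the interval name, column 5 the score.
    Coordinates are kept 0-based half-open.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated columns"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: unparseable score {fields[4]!r}"
                    ) from None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(repr(iv.score))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------

def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a tab-separated mutation table with a header naming all
    :class:`MutationRecord` fields (extra columns are ignored)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    return frame_to_records(df)


def write_mutation_table(
    records: Iterable[MutationRecord] | pd.DataFrame, path: str | Path
) -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, sep="\t", index=False)


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=MUTATION_COLUMNS)
    return pd.DataFrame(rows)[MUTATION_COLUMNS]


def frame_to_records(df: pd.DataFrame) -> list[MutationRecord]:
    return [
        MutationRecord(
            patient_id=str(r.patient_id), sample_id=str(r.sample_id),
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            t_depth=int(r.t_depth), t_alt=int(r.t_alt),
            n_depth=int(r.n_depth), n_alt=int(r.n_alt),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample matrix of log2-normalized expression.

    Rows are genes (first column holds gene ids), columns are samples.
    Raises on duplicated identifiers or non-finite values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated gene id(s): {dupes}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicated sample id(s)")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: expression matrix contains non-finite values")
    df.index.name = "gene_id"
    return df.astype(float)


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# signature catalogs
# ---------------------------------------------------------------------------

def read_signature_catalog(path: str | Path) -> pd.DataFrame:
    """Read a 96-context x K-signature catalog (TSV; first column holds the
    channel labels, e.g. ``A[C>A]A``).

    Each signature column must be nonnegative and sum to 1 within 1e-6
    (columns are renormalized to sum exactly to 1).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_signature_catalog(df, origin=str(path))


def validate_signature_catalog(df: pd.DataFrame, origin: str = "catalog") -> pd.DataFrame:
    from .signatures import SBS96_CHANNELS  # channel order lives with signatures

    if df.shape[0] != 96:
        raise ValueError(f"{origin}: expected 96 context rows, got {df.shape[0]}")
    if df.shape[1] < 1:
        raise ValueError(f"{origin}: catalog has no signature columns")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError(f"{origin}: catalog contains negative entries")
    sums = values.sum(axis=0)
    bad = np.abs(sums - 1.0) > 1e-6
    if bad.any():
        names = df.columns[bad].tolist()
        raise ValueError(
            f"{origin}: signature column(s) {names} do not sum to 1 within 1e-6"
        )
    df = df.astype(float) / sums
    if set(df.index) == set(SBS96_CHANNELS):
        df = df.loc[SBS96_CHANNELS]
    else:
        raise ValueError(
            f"{origin}: row labels are not the 96 trinucleotide channels"
        )
    return df


def write_signature_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index_label="channel")


# ---------------------------------------------------------------------------
# FASTA and gene models
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a reference FASTA into a chromosome-name -> uppercase-sequence map."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a TSV with columns gene_id, chrom, strand, tss,
    coding_intervals (semicolon-separated ``start-end`` pairs, 0-based
    half-open; empty for noncoding genes)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "coding_intervals": str})
    required = ["gene_id", "chrom", "strand", "tss", "coding_intervals"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    genes = []
    for r in df.itertuples(index=False):
        spans = []
        field = "" if pd.isna(r.coding_intervals) else str(r.coding_intervals)
        for token in filter(None, field.split(";")):
            s, e = token.split("-")
            spans.append(GenomicInterval(str(r.chrom), int(s), int(e)))
        genes.append(
            GeneModel(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss),
                      tuple(spans))
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "coding_intervals": ";".join(
                f"{iv.start}-{iv.end}" for iv in g.coding_intervals
            ),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss",
                                "coding_intervals"]).to_csv(path, sep="\t", index=False)
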