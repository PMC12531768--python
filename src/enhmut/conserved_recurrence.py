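"""Conserved-enhancer flagging, nearest-gene assignment and recurrence.

An enhancer is *conserved* when it overlaps (by at least 1 bp, half-open
semantics) any interval of a conserved-element set, e.g. mouse-human
orthologous enhancers.  Each conserved enhancer is assigned to its first
and second nearest genes within 500 kb, measured from the nearer enhancer
edge to the TSS (0 if the TSS lies inside the enhancer) — the same
distance convention used for the TSS window in :mod:`enhmut.region_model`.

A gene is *recurrently mutated* when passing mutations in any of its
assigned conserved enhancers accumulate in at least ``min_units`` distinct
samples (or patients).  Gene lists from independent cohorts can then be
intersected.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomicInterval
from .region_model import tss_to_interval_distance

__all__ = [
    "flag_conserved",
    "assign_nearest_genes",
    "build_enhancer_gene_map",
    "RecurrenceTable",
    "recurrence_table",
    "recurrent_genes",
    "cross_cohort_intersection",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


def flag_conserved(
    enhancers: Sequence[GenomicInterval],
    conserved: Sequence[GenomicInterval],
) -> np.ndarray:
    """Boolean flag per enhancer (input order preserved): True iff the
    enhancer shares >= 1 bp with any conserved interval."""
    flags = np.zeros(len(enhancers), dtype=bool)
    if not conserved or not enhancers:
        return flags
    cons_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in conserved:
        cons_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    index = {}
    for chrom, spans in cons_by_chrom.items():
        # merge to disjoint sorted spans so a binary search suffices
        spans.sort()
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        index[chrom] = (
            np.array([s for s, _ in merged]),
            np.array([e for _, e in merged]),
        )
    for i, iv in enumerate(enhancers):
        spans = index.get(iv.chrom)
        if spans is None:
            continue
        starts, ends = spans
        # overlap iff some conserved span starts before iv.end and ends after iv.start
        j = np.searchsorted(starts, iv.end, side="left") - 1
        flags[i] = j >= 0 and ends[j] > iv.start
    return flags


def assign_nearest_genes(
    enhancer: GenomicInterval,
    genes: Sequence[GeneModel],
    max_dist: int = 500_000,
) -> list[tuple[str, int]]:
    """First and second nearest genes (TSS anchor) within ``max_dist`` bp.

    Returns up to two ``(gene_id, distance)`` pairs sorted by distance,
    ties broken by gene_id; genes on other chromosomes or beyond
    ``max_dist`` are excluded.
    """
    candidates = [
        (tss_to_interval_distance(g.tss0, enhancer.start, enhancer.end), g.gene_id)
        for g in genes
        if g.chrom == enhancer.chrom
    ]
    eligible = sorted((d, gid) for d, gid in candidates if d <= max_dist)
    return [(gid, d) for d, gid in eligible[:2]]


def build_enhancer_gene_map(
    enhancers: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    max_dist: int = 500_000,
) -> dict[tuple[str, int, int], list[tuple[str, int]]]:
    """Nearest-two-genes assignment for every enhancer, keyed by
    ``(chrom, start, end)``."""
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    out = {}
    for iv in enhancers:
        out[(iv.chrom, iv.start, iv.end)] = assign_nearest_genes(
            iv, genes_by_chrom.get(iv.chrom, []), max_dist
        )
    return out


@dataclasses.dataclass
class RecurrenceTable:
    """Per-gene sets of mutated samples and patients (deduplicated)."""

    samples: dict[str, set[str]]
    patients: dict[str, set[str]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": gene,
                "n_samples": len(self.samples[gene]),
                "n_patients": len(self.patients[gene]),
                "samples": ",".join(sorted(self.samples[gene])),
                "patients": ",".join(sorted(self.patients[gene])),
            }
            for gene in sorted(self.samples)
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "n_samples", "n_patients", "samples",
                           "patients"]
        )


def enhancer_mutation_table(
    mutations: pd.DataFrame,
    enhancers: Sequence[GenomicInterval],
    conserved_flags: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Annotate mutations with the (disjoint) enhancer interval containing
    them; rows outside every enhancer are dropped.

    ``mutations`` needs columns ``patient_id``, ``sample_id``, ``chrom``,
    ``pos`` (1-based).  When ``conserved_flags`` is given (aligned with
    ``enhancers``), only mutations in conserved enhancers are kept.
    """
    keep = list(enhancers)
    if conserved_flags is not None:
        if len(conserved_flags) != len(keep):
            raise ValueError("conserved_flags must align with enhancers")
        keep = [iv for iv, f in zip(keep, conserved_flags) if f]
    index: dict[str, tuple[np.ndarray, np.ndarray, list[GenomicInterval]]] = {}
    for chrom in {iv.chrom for iv in keep}:
        ivs = sorted((iv for iv in keep if iv.chrom == chrom),
                     key=lambda iv: iv.start)
        index[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
            ivs,
        )
    rows = []
    for row in mutations.itertuples(index=False):
        entry = index.get(str(row.chrom))
        if entry is None:
            continue
        starts, ends, ivs = entry
        pos0 = int(row.pos) - 1
        j = int(np.searchsorted(starts, pos0, side="right")) - 1
        if j >= 0 and pos0 < ends[j]:
            d = row._asdict()
            d.update(enh_chrom=ivs[j].chrom, enh_start=ivs[j].start,
                     enh_end=ivs[j].end)
            rows.append(d)
    cols = list(mutations.columns) + ["enh_chrom", "enh_start", "enh_end"]
    return pd.DataFrame(rows, columns=cols)


def recurrence_table(
    enhancer_mutations: pd.DataFrame,
    gene_map: Mapping[tuple[str, int, int], Sequence[tuple[str, int]]],
) -> RecurrenceTable:
    """Accumulate mutated samples/patients per assigned gene.

    ``enhancer_mutations`` must carry columns ``patient_id``, ``sample_id``,
    ``enh_chrom``, ``enh_start``, ``enh_end`` — one row per passing mutation
    that falls in a conserved enhancer, annotated with that enhancer's
    coordinates.  Every gene assigned to the enhancer (up to two) accrues
    the sample and patient; mutations in enhancers with no assigned gene
    are tallied under the ``unassigned`` sentinel.
    """
    required = ["patient_id", "sample_id", "enh_chrom", "enh_start", "enh_end"]
    missing = [c for c in required if c not in enhancer_mutations.columns]
    if missing:
        raise ValueError(f"enhancer mutation table missing column(s): {missing}")
    samples: dict[str, set[str]] = {}
    patients: dict[str, set[str]] = {}
    for row in enhancer_mutations.itertuples(index=False):
        key = (str(row.enh_chrom), int(row.enh_start), int(row.enh_end))
        if key not in gene_map:
            raise KeyError(f"enhancer {key} absent from gene map")
        assigned = gene_map[key]
        targets = [gid for gid, _ in assigned] if assigned else [UNASSIGNED]
        for gene in targets:
            samples.setdefault(gene, set()).add(str(row.sample_id))
            patients.setdefault(gene, set()).add(str(row.patient_id))
    return RecurrenceTable(samples=samples, patients=patients)


def recurrent_genes(
    table: RecurrenceTable,
    min_units: int = 3,
    unit: str = "sample",
) -> list[str]:
    """Genes mutated in at least ``min_units`` distinct samples or patients,
    sorted by count descending then gene id; the ``unassigned`` sentinel is
    never reported."""
    if unit not in ("sample", "patient"):
        raise ValueError("unit must be 'sample' or 'patient'")
    sets = table.samples if unit == "sample" else table.patients
    hits = [
        (len(members), gene)
        for gene, members in sets.items()
        if gene != UNASSIGNED and len(members) >= min_units
    ]
    return [gene for _, gene in sorted(hits, key=lambda t: (-t[0], t[1]))]


def cross_cohort_intersection(
    list_a: Sequence[str], list_b: Sequence[str]
) -> list[str]:
    """Sorted intersection of two cohorts' recurrent-gene lists."""
    return sorted(set(list_a) & set(list_b))
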