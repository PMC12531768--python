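"""Somatic variant filter cascade for multi-region tumor/normal cohorts.

A candidate variant of one patient, observed across all of that patient's
tumor samples plus the matched normal, passes when every clause holds:

1. normal depth >= ``min_normal_depth`` (default 10)
2. normal alt reads <= ``max_normal_alt`` (default 2)
3. normal VAF < ``max_normal_vaf`` (default 0.02)
4. tumor depth >= ``min_tumor_depth_all_samples`` (default 20) in *all*
   tumor samples of the patient
5. at least one tumor sample with alt reads >= ``min_tumor_alt`` (default
   10) *and* VAF >= ``min_tumor_vaf`` (default 0.05) jointly

VAF is alt/depth, with the degenerate 0/0 defined as 0.  Clauses are
evaluated in the order above and the rejection reason names the first
clause that fails.

A passing variant is scored as *present* in any individual sample with at
least ``min_presence_reads`` supporting reads (default 1); the resulting
presence matrix feeds clonal/subclonal labeling.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clonality import PresenceMatrix
from .io_formats import MutationRecord

__all__ = [
    "FilterThresholds",
    "compute_vaf",
    "filter_patient_variants",
    "filter_cohort",
    "presence_matrix",
    "REJECTION_REASONS",
]

REJECTION_REASONS = (
    "normal depth",
    "normal alt",
    "normal VAF",
    "tumor depth",
    "tumor support",
)


@dataclasses.dataclass(frozen=True)
class FilterThresholds:
    min_normal_depth: int = 10
    max_normal_alt: int = 2
    max_normal_vaf: float = 0.02
    min_tumor_alt: int = 10
    min_tumor_vaf: float = 0.05
    min_tumor_depth_all_samples: int = 20
    min_presence_reads: int = 1

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            if getattr(self, field.name) < 0:
                raise ValueError(f"{field.name} must be nonnegative")
        for name in ("max_normal_vaf", "min_tumor_vaf"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def compute_vaf(alt: int, depth: int) -> float:
    """Variant allele frequency alt/depth; 0 when depth is 0."""
    if alt > depth:
        raise ValueError(f"alt ({alt}) exceeds depth ({depth})")
    if depth < 0 or alt < 0:
        raise ValueError("read counts must be nonnegative")
    return 0.0 if depth == 0 else alt / depth


VariantKey = tuple[str, str, int, str, str]  # (patient, chrom, pos, ref, alt)


def _group_by_variant(
    records: Iterable[MutationRecord],
) -> dict[VariantKey, list[MutationRecord]]:
    groups: dict[VariantKey, list[MutationRecord]] = defaultdict(list)
    for r in records:
        groups[r.variant_id].append(r)
    return dict(groups)


def filter_patient_variants(
    records: Sequence[MutationRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[set[VariantKey], dict[VariantKey, str]]:
    """Apply the filter cascade to one patient's variants.

    ``records`` holds one row per (variant, tumor sample); every variant
    must carry a row for every tumor sample of the patient (the all-samples
    depth clause is undefined otherwise).  Returns the passing variant-key
    set and, for each rejected variant, the first failed clause.
    """
    if not records:
        return set(), {}
    patients = {r.patient_id for r in records}
    if len(patients) > 1:
        raise ValueError(
            f"filter_patient_variants expects one patient, got {sorted(patients)}"
        )
    all_samples = {r.sample_id for r in records}
    groups = _group_by_variant(records)

    passing: set[VariantKey] = set()
    reasons: dict[VariantKey, str] = {}
    for key, rows in groups.items():
        seen = {r.sample_id for r in rows}
        if seen != all_samples:
            missing = sorted(all_samples - seen)
            raise ValueError(
                f"variant {key[1]}:{key[2]} {key[3]}>{key[4]} lacks rows for "
                f"tumor sample(s) {missing}"
            )
        if len(rows) != len(seen):
            raise ValueError(
                f"variant {key[1]}:{key[2]} has duplicated sample rows"
            )
        reason = _evaluate_variant(rows, thresholds)
        if reason is None:
            passing.add(key)
        else:
            reasons[key] = reason
    return passing, reasons


def _evaluate_variant(
    rows: Sequence[MutationRecord], th: FilterThresholds
) -> str | None:
    """First failed clause name, or None when the variant passes."""
    normal = rows[0]
    if normal.n_depth < th.min_normal_depth:
        return "normal depth"
    if normal.n_alt > th.max_normal_alt:
        return "normal alt"
    if compute_vaf(normal.n_alt, normal.n_depth) >= th.max_normal_vaf:
        return "normal VAF"
    if any(r.t_depth < th.min_tumor_depth_all_samples for r in rows):
        return "tumor depth"
    supported = any(
        r.t_alt >= th.min_tumor_alt
        and compute_vaf(r.t_alt, r.t_depth) >= th.min_tumor_vaf
        for r in rows
    )
    if not supported:
        return "tumor support"
    return None


def presence_matrix(
    records: Sequence[MutationRecord],
    passing: set[VariantKey],
    min_presence_reads: int = 1,
) -> PresenceMatrix:
    """Presence matrix of one patient's passing variants across samples.

    A variant is present in a sample when that sample carries at least
    ``min_presence_reads`` supporting reads.  Variants present in a passing
    variant's anchor sample are guaranteed >= min_tumor_alt reads, so every
    passing variant is present somewhere.
    """
    groups = _group_by_variant(records)
    samples = sorted({r.sample_id for r in records})
    keys = sorted(passing)
    present = np.zeros((len(keys), len(samples)), dtype=bool)
    sample_idx = {s: j for j, s in enumerate(samples)}
    for i, key in enumerate(keys):
        for r in groups[key]:
            if r.t_alt >= min_presence_reads:
                present[i, sample_idx[r.sample_id]] = True
    return PresenceMatrix(variants=keys, samples=samples, present=present)


def filter_cohort(
    records: Sequence[MutationRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[set[VariantKey], pd.DataFrame]:
    """Run the per-patient filter across a cohort table.

    Returns the union of passing variant keys and a tidy rejection table
    with columns patient_id, chrom, pos, ref, alt, reason.
    """
    by_patient: dict[str, list[MutationRecord]] = defaultdict(list)
    for r in records:
        by_patient[r.patient_id].append(r)
    passing: set[VariantKey] = set()
    rej_rows = []
    for patient in sorted(by_patient):
        p_pass, p_reasons = filter_patient_variants(by_patient[patient], thresholds)
        passing |= p_pass
        for (pid, chrom, pos, ref, alt), reason in sorted(p_reasons.items()):
            rej_rows.append(
                {"patient_id": pid, "chrom": chrom, "pos": pos,
                 "ref": ref, "alt": alt, "reason": reason}
            )
    rejected = pd.DataFrame(
        rej_rows, columns=["patient_id", "chrom", "pos", "ref", "alt", "reason"]
    )
    return passing, rejected
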