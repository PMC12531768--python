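"""Mutually exclusive genomic region model and per-region mutation burden.

The genome is partitioned into four labels — ``coding``, ``promoter``,
``enhancer`` and ``noncoding-NOS`` — with precedence
coding > promoter > enhancer > noncoding-NOS: base pairs claimed by a
higher-precedence label are clipped out of lower ones, and noncoding-NOS is
the remainder, so footprints always sum exactly to the genome size.

Enhancers enter the atlas after two upstream steps that mirror how an
H3K27ac peak atlas is reduced to candidate enhancers: a peak-score cutoff
(strictly greater than 50 by default) and a TSS-distance window (kept only
if the nearest transcription start site lies between 2 and 50 kb away;
peaks containing or abutting a TSS belong to promoter space, peaks further
than 50 kb are unassignable distal elements).

Distances from an interval to a TSS are measured from the nearer interval
edge: 0 if the TSS falls inside the interval, otherwise the number of base
pairs separating the TSS from the closest covered base.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .io_formats import GeneModel, GenomicInterval

__all__ = [
    "REGION_LABELS",
    "RegionAtlas",
    "select_enhancer_peaks",
    "apply_tss_window",
    "tss_to_interval_distance",
    "build_region_atlas",
    "classify_mutation",
    "classify_positions",
    "burden_per_mb",
    "merge_intervals",
    "subtract_intervals",
]

REGION_LABELS = ("coding", "promoter", "enhancer", "noncoding-NOS")


# ---------------------------------------------------------------------------
# interval algebra (pyranges-backed)
# ---------------------------------------------------------------------------

def _to_pyranges(intervals: Iterable[GenomicInterval]) -> pr.PyRanges:
    ivs = list(intervals)
    if not ivs:
        return pr.PyRanges(pd.DataFrame(columns=["Chromosome", "Start", "End"]))
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [iv.chrom for iv in ivs],
                "Start": [iv.start for iv in ivs],
                "End": [iv.end for iv in ivs],
            }
        )
    )


def _from_pyranges(g: pr.PyRanges) -> list[GenomicInterval]:
    df = g.df
    if df.empty:
        return []
    df = df.sort_values(["Chromosome", "Start", "End"])
    return [
        GenomicInterval(str(c), int(s), int(e))
        for c, s, e in zip(df.Chromosome, df.Start, df.End)
    ]


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    g = _to_pyranges(intervals)
    if g.df.empty:
        return []
    return _from_pyranges(g.merge())


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base pairs of ``a`` not covered by ``b`` (both merged first)."""
    ga = _to_pyranges(a)
    if ga.df.empty:
        return []
    gb = _to_pyranges(b)
    if gb.df.empty:
        return _from_pyranges(ga.merge())
    return _from_pyranges(ga.merge().subtract(gb.merge()))


# ---------------------------------------------------------------------------
# enhancer peak selection
# ---------------------------------------------------------------------------

def select_enhancer_peaks(
    peaks: Sequence[GenomicInterval], min_score: float = 50.0
) -> list[GenomicInterval]:
    """Keep peaks with score strictly greater than ``min_score`` and merge
    overlapping survivors."""
    for iv in peaks:
        if iv.score is None:
            raise ValueError(f"peak {iv.chrom}:{iv.start}-{iv.end} has no score")
    kept = [iv for iv in peaks if iv.score > min_score]
    return merge_intervals(kept)


def tss_to_interval_distance(tss0: int, start: int, end: int) -> int:
    """Distance (bp) from a 0-based TSS position to interval ``[start, end)``;
    0 if the TSS is inside, else the gap to the nearer covered base."""
    if start <= tss0 < end:
        return 0
    if tss0 < start:
        return start - tss0
    return tss0 - end + 1


def _nearest_tss_distances(
    peaks: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> np.ndarray:
    """Vectorized nearest-TSS edge distance for each peak (inf if the peak's
    chromosome carries no TSS)."""
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss0)
    tss_by_chrom = {c: np.array(sorted(v)) for c, v in tss_by_chrom.items()}

    out = np.full(len(peaks), np.inf)
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(peaks):
        by_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        T = tss_by_chrom.get(chrom)
        if T is None or len(T) == 0:
            continue
        starts = np.array([peaks[i].start for i in idxs])
        ends = np.array([peaks[i].end for i in idxs])
        pos = np.searchsorted(T, starts, side="left")
        dist = np.full(len(idxs), np.inf)
        inside = (pos < len(T)) & (T[np.minimum(pos, len(T) - 1)] < ends)
        dist[inside] = 0
        left_ok = pos > 0
        left = np.full(len(idxs), np.inf)
        left[left_ok] = starts[left_ok] - T[pos[left_ok] - 1]
        right_pos = np.searchsorted(T, ends, side="left")
        right_ok = right_pos < len(T)
        right = np.full(len(idxs), np.inf)
        right[right_ok] = T[right_pos[right_ok]] - ends[right_ok] + 1
        dist = np.where(inside, 0, np.minimum(left, right))
        out[idxs] = dist
    return out


def apply_tss_window(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    near_bp: int = 2_000,
    far_bp: int = 50_000,
) -> list[GenomicInterval]:
    """Keep peaks whose nearest-TSS distance lies in ``[near_bp, far_bp]``.

    Peaks closer than ``near_bp`` (including those containing a TSS) and
    peaks farther than ``far_bp`` from every TSS are excluded.
    """
    if not genes:
        raise ValueError("apply_tss_window requires at least one gene model")
    if near_bp >= far_bp:
        raise ValueError("near_bp must be smaller than far_bp")
    dist = _nearest_tss_distances(peaks, genes)
    return [iv for iv, d in zip(peaks, dist) if near_bp <= d <= far_bp]


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RegionAtlas:
    """Mutually exclusive labeled interval sets covering a genome.

    ``label_intervals`` maps each label to a sorted list of disjoint
    intervals; ``footprints`` holds the total bp per label and sums exactly
    to ``genome_size``.
    """

    chrom_sizes: dict[str, int]
    label_intervals: dict[str, list[GenomicInterval]]
    footprints: dict[str, int]

    _index: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = dataclasses.field(
        default=None, repr=False, compare=False
    )

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def __post_init__(self) -> None:
        index: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for label, ivs in self.label_intervals.items():
            per_chrom: dict[str, list[tuple[int, int]]] = {}
            for iv in ivs:
                per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            index[label] = {
                c: (
                    np.array([s for s, _ in sorted(spans)]),
                    np.array([e for _, e in sorted(spans)]),
                )
                for c, spans in per_chrom.items()
            }
        self._index = index


def build_region_atlas(
    genes: Sequence[GeneModel],
    enhancer_set: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    promoter_halfwidth: int = 2_000,
) -> RegionAtlas:
    """Assemble the four-label atlas with precedence
    coding > promoter > enhancer > noncoding-NOS.

    ``enhancer_set`` is expected to be score-filtered and TSS-window
    filtered already.  Promoters are TSS +/- ``promoter_halfwidth`` bp
    (inclusive on both sides), clipped to chromosome bounds.
    """
    chrom_sizes = dict(chrom_sizes)

    def _check(ivs: Iterable[GenomicInterval], what: str) -> None:
        for iv in ivs:
            if iv.chrom not in chrom_sizes:
                raise ValueError(f"{what} interval on unknown chromosome {iv.chrom}")
            if iv.end > chrom_sizes[iv.chrom]:
                raise ValueError(
                    f"{what} interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome size {chrom_sizes[iv.chrom]}"
                )

    coding_raw = [iv for g in genes for iv in g.coding_intervals]
    promoter_raw = []
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        start = max(0, g.tss0 - promoter_halfwidth)
        end = min(chrom_sizes[g.chrom], g.tss0 + promoter_halfwidth + 1)
        promoter_raw.append(GenomicInterval(g.chrom, start, end))
    _check(coding_raw, "coding")
    _check(enhancer_set, "enhancer")

    coding = merge_intervals(coding_raw)
    promoter = subtract_intervals(promoter_raw, coding)
    higher = coding + promoter
    enhancer = subtract_intervals(enhancer_set, higher)
    genome = [GenomicInterval(c, 0, size) for c, size in chrom_sizes.items()]
    nos = subtract_intervals(genome, higher + enhancer)

    label_intervals = {
        "coding": coding,
        "promoter": promoter,
        "enhancer": enhancer,
        "noncoding-NOS": nos,
    }
    footprints = {
        label: int(sum(iv.length for iv in ivs))
        for label, ivs in label_intervals.items()
    }
    atlas = RegionAtlas(chrom_sizes, label_intervals, footprints)
    assert sum(footprints.values()) == atlas.genome_size
    return atlas


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_positions(
    atlas: RegionAtlas, chroms: Sequence[str], positions: Sequence[int]
) -> np.ndarray:
    """Vectorized labeling of 1-based positions; returns an object array of
    labels aligned with the input."""
    chroms = np.asarray(chroms, dtype=object)
    pos0 = np.asarray(positions, dtype=np.int64) - 1
    unknown = set(chroms) - set(atlas.chrom_sizes)
    if unknown:
        raise KeyError(f"chromosome(s) absent from atlas: {sorted(unknown)}")
    labels = np.full(len(chroms), None, dtype=object)
    for chrom in np.unique(chroms):
        sel = np.where(chroms == chrom)[0]
        p = pos0[sel]
        if (p < 0).any() or (p >= atlas.chrom_sizes[str(chrom)]).any():
            raise ValueError(f"position outside chromosome {chrom}")
        assigned = np.zeros(len(sel), dtype=bool)
        for label in REGION_LABELS:
            spans = atlas._index[label].get(str(chrom))
            if spans is None:
                continue
            starts, ends = spans
            idx = np.searchsorted(starts, p, side="right") - 1
            hit = (idx >= 0) & (p < ends[np.maximum(idx, 0)])
            hit &= ~assigned
            labels[sel[hit]] = label
            assigned |= hit
        if not assigned.all():
            raise AssertionError(
                f"atlas does not cover chromosome {chrom} completely"
            )
    return labels


def classify_mutation(atlas: RegionAtlas, mutation) -> str:
    """Label of the single base ``[pos-1, pos)`` of one mutation record."""
    return str(classify_positions(atlas, [mutation.chrom], [mutation.pos])[0])


# ---------------------------------------------------------------------------
# burden
# ---------------------------------------------------------------------------

def burden_per_mb(
    classified: pd.DataFrame,
    atlas: RegionAtlas,
    group_keys: Sequence[str] = ("sample_id",),
) -> pd.DataFrame:
    """Mutation burden (mut/Mb) per group per region label.

    ``classified`` must carry a ``label`` column plus every grouping column
    (``sample_id`` and optionally ``clonality``).  Groups observed in the
    input report a rate for all four labels, filling zero counts; the
    denominator is the atlas footprint of the label, identical for every
    sample.
    """
    group_keys = list(group_keys)
    required = group_keys + ["label"]
    missing = [c for c in required if c not in classified.columns]
    if missing:
        raise ValueError(f"classified table missing column(s): {missing}")
    bad = set(classified["label"]) - set(REGION_LABELS)
    if bad:
        raise ValueError(f"unknown region label(s): {sorted(bad)}")

    counts = (
        classified.groupby(group_keys + ["label"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    groups = classified[group_keys].drop_duplicates()
    full = groups.merge(pd.DataFrame({"label": REGION_LABELS}), how="cross")
    full = full.merge(counts, on=group_keys + ["label"], how="left")
    full["count"] = full["count"].fillna(0).astype(int)
    full["footprint_bp"] = full["label"].map(atlas.footprints)
    zero_fp = (full["footprint_bp"] == 0) & (full["count"] > 0)
    if zero_fp.any():
        raise ValueError(
            "mutations observed in label(s) with zero footprint: "
            f"{sorted(full.loc[zero_fp, 'label'].unique())}"
        )
    full["rate_per_mb"] = np.where(
        full["footprint_bp"] > 0,
        full["count"] / (full["footprint_bp"] / 1e6),
        0.0,
    )
    return full.sort_values(group_keys + ["label"]).reset_index(drop=True)
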