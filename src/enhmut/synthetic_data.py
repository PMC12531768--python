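"""Synthetic multi-region tumor cohorts with planted ground truth.

The generator emulates the structure of a multi-region whole-genome study
of pancreatic cancer: a small reference genome with gene models, scored
enhancer peaks and conserved elements; per-patient somatic variants with
region-specific rates, a clonal/subclonal partition, a treatment burden
multiplier, and region-specific signature mixtures; decoy rows that
violate the somatic filter; planted recurrent conserved-enhancer mutations
with accompanying expression shifts.  Every downstream stage of the
pipeline can be scored against the recorded truth.

Default parameters are the study conditions: 10 patients with 8 tumor
samples each, untreated region rates equal to the reported untreated
medians (coding 1.30, promoter 1.86, enhancer 1.52, noncoding-NOS 2.48
mut/Mb), a 3.8-fold treatment multiplier on 60% of patients, 80% clonal
mutations, a 14.5% conserved-enhancer fraction, 20% decoy rows, tumor and
normal target coverages of 80x and 40x, and a planted expression shift of
-3.32 log2 units (about 10-fold down).

Two placement modes exist.  The default, ``context``, samples each
mutation's trinucleotide channel from the region's signature mixture and
then a uniform genomic position matching that context, which makes
signature refitting recoverable; it requires the reference sequence.  The
``uniform`` mode samples positions uniformly within region footprints
without touching sequence, which scales to multi-gigabase footprints for
burden-recovery experiments.

All outputs are deterministic functions of the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomicInterval, MUTATION_COLUMNS
from .region_model import (
    REGION_LABELS,
    RegionAtlas,
    apply_tss_window,
    build_region_atlas,
    select_enhancer_peaks,
)
from .signatures import SUBSTITUTIONS, synthetic_catalog
from .variant_filtering import FilterThresholds
from .conserved_recurrence import build_enhancer_gene_map

__all__ = [
    "SyntheticGenome",
    "PlantedEvent",
    "CohortTruth",
    "simulate_genome",
    "simulate_cohort",
    "simulate_expression",
    "mutations_from_channels",
    "DEFAULT_REGION_RATES",
    "DEFAULT_SIGNATURE_MIXTURE",
]

#: Untreated per-region mutation rates (mut/Mb), the study conditions.
DEFAULT_REGION_RATES = {
    "coding": 1.30,
    "promoter": 1.86,
    "enhancer": 1.52,
    "noncoding-NOS": 2.48,
}

#: Region-specific signature mixtures: enhancers are enriched for SBS39
#: and depleted for SBS1/SBS8/SBS40/SBS41 relative to the other regions.
DEFAULT_SIGNATURE_MIXTURE = {
    "coding": {"SBS1": 0.25, "SBS5": 0.30, "SBS8": 0.15, "SBS40": 0.20,
               "SBS41": 0.10},
    "promoter": {"SBS1": 0.25, "SBS5": 0.30, "SBS8": 0.15, "SBS40": 0.20,
                 "SBS41": 0.10},
    "enhancer": {"SBS39": 0.45, "SBS5": 0.25, "SBS18": 0.20, "SBS1": 0.10},
    "noncoding-NOS": {"SBS1": 0.25, "SBS5": 0.30, "SBS8": 0.15, "SBS40": 0.20,
                      "SBS41": 0.10},
}

_BASES = "ACGT"
_SUB_TARGET = {s: s[2] for s in SUBSTITUTIONS}  # pyrimidine-strand alt base
_COMP_CODE = np.array([3, 2, 1, 0])  # A<->T, C<->G on 0..3 codes


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticGenome:
    """A simulated reference with gene models, enhancer peaks and conserved
    elements, plus the generator's own bookkeeping of which peaks survive
    the score cutoff and TSS window and which of those are conserved."""

    chrom_sizes: dict[str, int]
    sequences: dict[str, str] | None
    genes: list[GeneModel]
    enhancer_peaks: list[GenomicInterval]  # raw scored peaks
    enhancers: list[GenomicInterval]  # score- and window-filtered, merged
    conserved: list[GenomicInterval]
    conserved_flags: np.ndarray  # per entry of `enhancers`

    def atlas(self, promoter_halfwidth: int = 2_000) -> RegionAtlas:
        return build_region_atlas(
            self.genes, self.enhancers, self.chrom_sizes, promoter_halfwidth
        )


def simulate_genome(
    n_chroms: int = 2,
    chrom_len: int = 1_000_000,
    n_genes: int = 40,
    n_enhancers: int = 120,
    n_conserved: int | None = None,
    seed: int = 0,
    *,
    conserved_fraction: float | None = 0.145,
    tss_window_fraction: float = 0.8,
    enhancer_width: int = 800,
    coding_bp_per_gene: int = 1_500,
    with_sequence: bool = True,
) -> SyntheticGenome:
    """Simulate a reference genome with annotation.

    A configurable fraction of enhancer peaks is aimed at the 2-50 kb TSS
    window (the rest are dropped onto a TSS, guaranteeing exclusion); each
    window-passing, score-passing enhancer is flagged conserved with
    probability ``conserved_fraction`` (or exactly ``n_conserved`` of them
    when a count is given) and receives an overlapping conserved element.
    Deterministic given ``seed``; raises when the requested features cannot
    be packed into the chromosomes.
    """
    if min(n_chroms, chrom_len, n_genes, n_enhancers) < 1:
        raise ValueError("all counts must be >= 1")
    if (n_conserved is None) == (conserved_fraction is None):
        raise ValueError("give exactly one of n_conserved / conserved_fraction")
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    chrom_sizes = {c: int(chrom_len) for c in chrom_names}

    # --- genes, packed into per-chromosome slots
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                 for i in range(n_chroms)]
    exon_len = max(coding_bp_per_gene // 2, 1)
    gene_extent = 2_000 + 200 + 2 * exon_len + 500 + 200  # promoter+exons+margins
    genes: list[GeneModel] = []
    for chrom, count in zip(chrom_names, per_chrom):
        if count == 0:
            continue
        slot = chrom_len // count
        if slot < gene_extent + 2_000:
            raise ValueError(
                f"cannot pack {count} genes of extent {gene_extent} bp into "
                f"{chrom} ({chrom_len} bp)"
            )
        for j in range(count):
            lo = j * slot + 2_000
            hi = (j + 1) * slot - gene_extent
            tss0 = int(rng.integers(lo, max(lo + 1, hi)))
            strand = "+" if rng.random() < 0.5 else "-"
            # exons always placed downstream in coordinate space; strand is
            # annotation only (context placement is strand-symmetric)
            e1 = GenomicInterval(chrom, tss0 + 200, tss0 + 200 + exon_len)
            e2 = GenomicInterval(chrom, e1.end + 500, e1.end + 500 + exon_len)
            genes.append(
                GeneModel(f"G{len(genes):04d}", chrom, strand, tss0 + 1, (e1, e2))
            )

    # --- enhancer peaks
    near, far = 2_000, 50_000
    if chrom_len < far + enhancer_width + 4_000:
        raise ValueError("chromosomes too short for the 2-50 kb TSS window")
    peaks: list[GenomicInterval] = []
    in_window = rng.random(n_enhancers) < tss_window_fraction
    gene_pick = rng.integers(0, len(genes), size=n_enhancers)
    for i in range(n_enhancers):
        g = genes[gene_pick[i]]
        size = chrom_sizes[g.chrom]
        if in_window[i]:
            d = int(rng.integers(near + 500, far - enhancer_width - 500))
            side = 1 if rng.random() < 0.5 else -1
            start = g.tss0 + d if side > 0 else g.tss0 - d - enhancer_width
        else:
            start = g.tss0 - enhancer_width // 2  # contains the TSS -> excluded
        start = max(0, min(start, size - enhancer_width))
        score = float(rng.uniform(10, 150))
        peaks.append(
            GenomicInterval(g.chrom, start, start + enhancer_width,
                            name=f"peak{i:05d}", score=score)
        )

    selected = select_enhancer_peaks(peaks, min_score=50.0)
    enhancers = apply_tss_window(selected, genes, near, far)

    # --- conserved elements, each a sub-interval of a flagged enhancer
    if n_conserved is not None:
        if n_conserved > len(enhancers):
            raise ValueError(
                f"n_conserved={n_conserved} exceeds {len(enhancers)} enhancers"
            )
        flags = np.zeros(len(enhancers), dtype=bool)
        if n_conserved:
            flags[rng.choice(len(enhancers), size=n_conserved, replace=False)] = True
    else:
        flags = rng.random(len(enhancers)) < conserved_fraction
    conserved = []
    for iv, flagged in zip(enhancers, flags):
        if not flagged:
            continue
        width = min(200, iv.length)
        mid = (iv.start + iv.end) // 2
        start = max(iv.start, mid - width // 2)
        conserved.append(GenomicInterval(iv.chrom, start, start + width))

    sequences = None
    if with_sequence:
        sequences = {
            c: "".join(np.array(list(_BASES))[rng.integers(0, 4, size)])
            for c, size in chrom_sizes.items()
        }

    return SyntheticGenome(
        chrom_sizes=chrom_sizes,
        sequences=sequences,
        genes=genes,
        enhancer_peaks=peaks,
        enhancers=enhancers,
        conserved=conserved,
        conserved_flags=flags,
    )


# ---------------------------------------------------------------------------
# trinucleotide-context position index
# ---------------------------------------------------------------------------

class _ContextIndex:
    """Per-(label, pyrimidine-context) buckets of genomic positions."""

    def __init__(self, genome: SyntheticGenome, atlas: RegionAtlas) -> None:
        if genome.sequences is None:
            raise ValueError("context placement requires a genome with sequence")
        self.chroms = list(genome.chrom_sizes)
        self.codes: dict[str, np.ndarray] = {}
        buckets: dict[tuple[str, int], list[np.ndarray]] = {}
        chrom_of: dict[tuple[str, int], list[np.ndarray]] = {}
        for ci, chrom in enumerate(self.chroms):
            seq = genome.sequences[chrom]
            code = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            lut = np.zeros(256, dtype=np.int8)
            for b, v in zip(b"ACGT", range(4)):
                lut[b] = v
            code = lut[code]
            self.codes[chrom] = code
            n = len(code)
            if n < 3:
                continue
            center = code[1:-1]
            left = code[:-2]
            right = code[2:]
            pyr = (center == 1) | (center == 3)
            cen32 = np.where(
                pyr, np.where(center == 1, 0, 1),
                np.where(center == 2, 0, 1),  # comp(G)=C, comp(A)=T
            )
            l32 = np.where(pyr, left, _COMP_CODE[right])
            r32 = np.where(pyr, right, _COMP_CODE[left])
            ctx32 = cen32 * 16 + l32 * 4 + r32
            # region label per interior position
            label_arr = np.full(n, -1, dtype=np.int8)
            for li, label in enumerate(REGION_LABELS):
                for iv in atlas.label_intervals[label]:
                    if iv.chrom == chrom:
                        label_arr[iv.start:iv.end] = li
            pos = np.arange(1, n - 1)
            key_arr = label_arr[1:-1].astype(np.int32) * 32 + ctx32
            order = np.argsort(key_arr, kind="stable")
            sorted_keys = key_arr[order]
            bounds = np.searchsorted(
                sorted_keys, np.arange(len(REGION_LABELS) * 32 + 1) * 1
            )
            for li in range(len(REGION_LABELS)):
                for ctx in range(32):
                    k = li * 32 + ctx
                    lo, hi = bounds[k], bounds[k + 1]
                    if hi > lo:
                        buckets.setdefault((REGION_LABELS[li], ctx), []).append(
                            pos[order[lo:hi]]
                        )
                        chrom_of.setdefault((REGION_LABELS[li], ctx), []).append(
                            np.full(hi - lo, ci, dtype=np.int32)
                        )
        self.positions = {k: np.concatenate(v) for k, v in buckets.items()}
        self.pos_chrom = {k: np.concatenate(v) for k, v in chrom_of.items()}

    def sample(
        self, label: str, channel: int, rng: np.random.Generator
    ) -> tuple[str, int, str, str]:
        """Uniform (chrom, 1-based pos, ref, alt) realizing a channel in a
        region label."""
        si, ctx16 = divmod(channel, 16)
        ctx32 = (0 if si < 3 else 1) * 16 + ctx16
        key = (label, ctx32)
        if key not in self.positions:
            raise ValueError(
                f"no genomic position with context {ctx32} in label {label}"
            )
        j = int(rng.integers(0, len(self.positions[key])))
        chrom = self.chroms[int(self.pos_chrom[key][j])]
        pos0 = int(self.positions[key][j])
        ref_code = int(self.codes[chrom][pos0])
        ref = _BASES[ref_code]
        target = _SUB_TARGET[SUBSTITUTIONS[si]]
        if ref in "CT":
            alt = target
        else:
            alt = _BASES[_COMP_CODE[_BASES.index(target)]]
        return chrom, pos0 + 1, ref, alt


def mutations_from_channels(
    genome: SyntheticGenome,
    channels: Sequence[int],
    seed: int,
    atlas: RegionAtlas | None = None,
    label: str = "noncoding-NOS",
) -> pd.DataFrame:
    """Place one mutation per requested channel uniformly among matching
    positions of one region label; returns a single-sample mutation table.

    Utility for spectrum/refitting experiments where only the channel
    composition matters.
    """
    atlas = atlas or genome.atlas()
    index = _ContextIndex(genome, atlas)
    rng = np.random.default_rng(seed)
    rows = []
    for ch in channels:
        chrom, pos, ref, alt = index.sample(label, int(ch), rng)
        rows.append(
            {"patient_id": "P00", "sample_id": "P00_S1", "chrom": chrom,
             "pos": pos, "ref": ref, "alt": alt, "t_depth": 80, "t_alt": 30,
             "n_depth": 40, "n_alt": 0}
        )
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlantedEvent:
    """A recurrent conserved-enhancer mutation with an expression effect."""

    gene_id: str
    enhancer: GenomicInterval
    mutant_samples: tuple[str, ...]
    log2_shift: float


@dataclasses.dataclass
class CohortTruth:
    """Generator bookkeeping sufficient to score every pipeline stage."""

    region_rates: dict[str, float]
    clonal_fraction: float
    treatment_multiplier: float
    treated_patients: set[str]
    signature_mixture: dict[str, dict[str, float]]
    samples_by_patient: dict[str, list[str]]
    somatic_keys: set[tuple]
    decoy_keys: set[tuple]
    assignments: dict[tuple, frozenset]  # variant key -> present sample set
    labels: dict[tuple, str]  # variant key -> region label
    channels: dict[tuple, int]  # variant key -> SBS channel (context mode)
    planted_enhancer_events: list[PlantedEvent]
    coding_mutant_samples: dict[str, set[str]]
    atlas: RegionAtlas

    @property
    def clonal_set(self) -> set[tuple]:
        return {
            key for key, present in self.assignments.items()
            if len(present) == len(self.samples_by_patient[key[0]])
        }

    @property
    def all_samples(self) -> list[str]:
        return [s for p in sorted(self.samples_by_patient)
                for s in self.samples_by_patient[p]]

    def per_sample_region_counts(self) -> pd.DataFrame:
        rows = []
        for key, present in self.assignments.items():
            for s in present:
                rows.append({"sample_id": s, "label": self.labels[key]})
        df = pd.DataFrame(rows)
        return (
            df.groupby(["sample_id", "label"]).size().rename("count").reset_index()
        )


def _nb_draw(rng: np.random.Generator, mean: float, size=None, dispersion=10.0):
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


class _UniformIndex:
    """Uniform position sampling within a label's footprint (no sequence)."""

    def __init__(self, atlas: RegionAtlas) -> None:
        self.tables = {}
        for label in REGION_LABELS:
            ivs = atlas.label_intervals[label]
            lengths = np.array([iv.length for iv in ivs], dtype=np.int64)
            self.tables[label] = (ivs, np.cumsum(lengths))

    def sample(self, label: str, rng: np.random.Generator) -> tuple[str, int]:
        ivs, cum = self.tables[label]
        if len(ivs) == 0 or cum[-1] == 0:
            raise ValueError(f"label {label} has zero footprint")
        offset = int(rng.integers(0, cum[-1]))
        i = int(np.searchsorted(cum, offset, side="right"))
        within = offset - (cum[i - 1] if i > 0 else 0)
        return ivs[i].chrom, ivs[i].start + within + 1  # 1-based


def _proper_subset(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform nonempty proper subset of n >= 2 samples (as a bool mask)."""
    while True:
        mask = rng.random(n) < 0.5
        if 0 < mask.sum() < n:
            return mask


def simulate_cohort(
    genome: SyntheticGenome,
    n_patients: int = 10,
    samples_per_patient: int = 8,
    region_rates: Mapping[str, float] | None = None,
    clonal_fraction: float = 0.8,
    treatment_multiplier: float = 3.8,
    signature_mixture: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    *,
    treated_fraction: float = 0.6,
    decoy_fraction: float = 0.2,
    tumor_coverage: float = 80.0,
    normal_coverage: float = 40.0,
    thresholds: FilterThresholds = FilterThresholds(),
    placement: str = "context",
    catalog: pd.DataFrame | None = None,
    n_planted_events: int = 2,
    planted_shift: float = -3.32,
    planted_mutant_samples: int = 4,
    planted_mutant_patients: int = 3,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate the somatic mutation tables of a multi-region cohort.

    Returns one tidy table with a row per (variant, tumor sample) — zero
    alt reads mark absence — and the :class:`CohortTruth` needed to score
    filtering, clonality, burden, signatures, recurrence and association.

    True somatic variants are constructed to pass the filter thresholds
    (anchor sample forced above the tumor-support clause, all depths above
    the coverage clauses); decoy rows (``decoy_fraction`` of all variants)
    are constructed to violate exactly one clause each.  Treated patients
    have all region rates multiplied by ``treatment_multiplier``.
    """
    if samples_per_patient < 2:
        raise ValueError("clonality needs >= 2 samples per patient")
    if not 0 <= clonal_fraction <= 1:
        raise ValueError("clonal_fraction must lie in [0, 1]")
    region_rates = dict(region_rates or DEFAULT_REGION_RATES)
    if set(region_rates) != set(REGION_LABELS):
        raise ValueError(f"region_rates must cover {REGION_LABELS}")
    if any(r <= 0 for r in region_rates.values()):
        raise ValueError("all region rates must be > 0")
    mixture = {
        label: dict(m) for label, m in
        (signature_mixture or DEFAULT_SIGNATURE_MIXTURE).items()
    }
    if placement not in ("context", "uniform"):
        raise ValueError("placement must be 'context' or 'uniform'")

    rng = np.random.default_rng(seed)
    atlas = genome.atlas()
    catalog = catalog if catalog is not None else synthetic_catalog()

    if placement == "context":
        ctx_index = _ContextIndex(genome, atlas)
        channel_dists = {}
        for label in REGION_LABELS:
            w = pd.Series(mixture[label], dtype=float)
            if abs(w.sum() - 1.0) > 1e-6:
                raise ValueError(f"signature mixture for {label} must sum to 1")
            channel_dists[label] = (catalog[w.index].to_numpy() @ w.to_numpy())
    else:
        uni_index = _UniformIndex(atlas)

    n_treated = int(round(treated_fraction * n_patients))
    patients = [f"P{i + 1:02d}" for i in range(n_patients)]
    treated = set(patients[:n_treated])
    samples_by_patient = {
        p: [f"{p}_S{j + 1}" for j in range(samples_per_patient)] for p in patients
    }

    footprint_mb = {l: atlas.footprints[l] / 1e6 for l in REGION_LABELS}

    rows: list[dict] = []
    somatic_keys: set[tuple] = set()
    decoy_keys: set[tuple] = set()
    assignments: dict[tuple, frozenset] = {}
    labels: dict[tuple, str] = {}
    channels: dict[tuple, int] = {}
    used_positions: set[tuple[str, str, int]] = set()

    def _position(label: str) -> tuple[str, int, str, str, int]:
        if placement == "context":
            ch = int(rng.choice(96, p=channel_dists[label] /
                                channel_dists[label].sum()))
            chrom, pos, ref, alt = ctx_index.sample(label, ch, rng)
            return chrom, pos, ref, alt, ch
        chrom, pos = uni_index.sample(label, rng)
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        return chrom, pos, str(ref), str(alt), -1

    def _emit_variant(
        patient: str, chrom: str, pos: int, ref: str, alt: str,
        present: Sequence[str],
    ) -> tuple:
        """Rows for one passing somatic variant across all patient samples."""
        key = (patient, chrom, pos, ref, alt)
        samples = samples_by_patient[patient]
        anchor = present[int(rng.integers(0, len(present)))]
        n_depth = max(int(_nb_draw(rng, normal_coverage)),
                      thresholds.min_normal_depth)
        vaf = rng.uniform(0.2, 0.6) if len(present) == len(samples) \
            else rng.uniform(0.1, 0.45)
        for s in samples:
            t_depth = max(int(_nb_draw(rng, tumor_coverage)),
                          thresholds.min_tumor_depth_all_samples)
            if s in present:
                t_alt = int(rng.binomial(t_depth, vaf))
                t_alt = min(max(t_alt, 1), t_depth)
                if s == anchor:
                    floor = max(thresholds.min_tumor_alt,
                                math.ceil(thresholds.min_tumor_vaf * t_depth))
                    t_alt = min(max(t_alt, floor), t_depth)
            else:
                t_alt = 0
            rows.append(
                {"patient_id": patient, "sample_id": s, "chrom": chrom,
                 "pos": pos, "ref": ref, "alt": alt, "t_depth": t_depth,
                 "t_alt": t_alt, "n_depth": n_depth, "n_alt": 0}
            )
        return key

    # --- true somatic variants per patient
    for patient in patients:
        mult = treatment_multiplier if patient in treated else 1.0
        samples = samples_by_patient[patient]
        for label in REGION_LABELS:
            lam = region_rates[label] * mult * footprint_mb[label]
            n_clonal = rng.poisson(clonal_fraction * lam)
            n_sub = rng.poisson(2.0 * (1.0 - clonal_fraction) * lam)
            for kind, count in (("clonal", n_clonal), ("subclonal", n_sub)):
                for _ in range(count):
                    while True:
                        chrom, pos, ref, alt, ch = _position(label)
                        if (patient, chrom, pos) not in used_positions:
                            break
                    used_positions.add((patient, chrom, pos))
                    if kind == "clonal":
                        present = list(samples)
                    else:
                        mask = _proper_subset(rng, len(samples))
                        present = [s for s, m in zip(samples, mask) if m]
                    key = _emit_variant(patient, chrom, pos, ref, alt, present)
                    somatic_keys.add(key)
                    assignments[key] = frozenset(present)
                    labels[key] = label
                    if ch >= 0:
                        channels[key] = ch

    # --- planted recurrent conserved-enhancer events
    planted_events = _plant_enhancer_events(
        genome, atlas, rng, n_planted_events, planted_shift,
        planted_mutant_samples, planted_mutant_patients, samples_by_patient,
        used_positions, _emit_variant, somatic_keys, assignments, labels,
    )

    # --- decoys violating the filter
    n_true = len(somatic_keys)
    n_decoys = int(round(n_true * decoy_fraction / max(1e-9, 1 - decoy_fraction)))
    decoy_types = ["germline", "normal_coverage", "tumor_coverage", "low_support"]
    for d in range(n_decoys):
        patient = patients[int(rng.integers(0, n_patients))]
        samples = samples_by_patient[patient]
        kind = decoy_types[d % len(decoy_types)]
        label = REGION_LABELS[int(rng.integers(0, 4))]
        while True:
            chrom, pos, ref, alt, _ = _position(label)
            if (patient, chrom, pos) not in used_positions:
                break
        used_positions.add((patient, chrom, pos))
        key = (patient, chrom, pos, ref, alt)
        decoy_keys.add(key)
        n_depth = max(int(_nb_draw(rng, normal_coverage)),
                      thresholds.min_normal_depth)
        n_alt = 0
        if kind == "germline":
            n_alt = max(thresholds.max_normal_alt + 1,
                        int(rng.binomial(n_depth, 0.5)))
            n_alt = min(n_alt, n_depth)
        elif kind == "normal_coverage":
            n_depth = int(rng.integers(0, thresholds.min_normal_depth))
        bad_sample = samples[int(rng.integers(0, len(samples)))]
        for s in samples:
            t_depth = max(int(_nb_draw(rng, tumor_coverage)),
                          thresholds.min_tumor_depth_all_samples)
            t_alt = int(rng.binomial(t_depth, 0.4))
            if kind == "tumor_coverage" and s == bad_sample:
                t_depth = int(rng.integers(0,
                                           thresholds.min_tumor_depth_all_samples))
                t_alt = min(t_alt, t_depth)
            elif kind == "low_support":
                t_alt = int(rng.integers(0, thresholds.min_tumor_alt))
            t_alt = min(t_alt, t_depth)
            n_alt_row = min(n_alt, n_depth)
            rows.append(
                {"patient_id": patient, "sample_id": s, "chrom": chrom,
                 "pos": pos, "ref": ref, "alt": alt, "t_depth": t_depth,
                 "t_alt": t_alt, "n_depth": n_depth, "n_alt": n_alt_row}
            )

    # --- coding-mutant samples per gene (for expression eligibility)
    coding_mutants: dict[str, set[str]] = {}
    coding_index = []
    for g in genome.genes:
        for iv in g.coding_intervals:
            coding_index.append((iv.chrom, iv.start, iv.end, g.gene_id))
    for key, label in labels.items():
        if label != "coding":
            continue
        _, chrom, pos, _, _ = key
        pos0 = pos - 1
        for c, s, e, gid in coding_index:
            if c == chrom and s <= pos0 < e:
                coding_mutants.setdefault(gid, set()).update(assignments[key])
                break

    table = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    table = table.sort_values(
        ["patient_id", "chrom", "pos", "alt", "sample_id"]
    ).reset_index(drop=True)
    truth = CohortTruth(
        region_rates=region_rates,
        clonal_fraction=clonal_fraction,
        treatment_multiplier=treatment_multiplier,
        treated_patients=treated,
        signature_mixture=mixture,
        samples_by_patient=samples_by_patient,
        somatic_keys=somatic_keys,
        decoy_keys=decoy_keys,
        assignments=assignments,
        labels=labels,
        channels=channels,
        planted_enhancer_events=planted_events,
        coding_mutant_samples=coding_mutants,
        atlas=atlas,
    )
    return table, truth


def _plant_enhancer_events(
    genome, atlas, rng, n_events, shift, n_samples, n_patients_wanted,
    samples_by_patient, used_positions, emit_variant, somatic_keys,
    assignments, labels,
) -> list[PlantedEvent]:
    """Plant recurrent mutations in conserved, gene-assigned enhancers."""
    if n_events == 0:
        return []
    conserved_enh = [
        iv for iv, f in zip(genome.enhancers, genome.conserved_flags) if f
    ]
    gene_map = build_enhancer_gene_map(conserved_enh, genome.genes)
    candidates = [
        iv for iv in conserved_enh
        if gene_map[(iv.chrom, iv.start, iv.end)]
    ]
    if len(candidates) < n_events:
        raise ValueError(
            f"only {len(candidates)} gene-assigned conserved enhancers "
            f"available for {n_events} planted events"
        )
    # enhancer-label sub-intervals of each candidate (clip of coding/promoter)
    enh_spans = {
        (iv.chrom, iv.start, iv.end): [
            a for a in atlas.label_intervals["enhancer"]
            if a.chrom == iv.chrom and a.start < iv.end and a.end > iv.start
            and max(a.start, iv.start) < min(a.end, iv.end)
        ]
        for iv in candidates
    }
    candidates = [iv for iv in candidates if enh_spans[(iv.chrom, iv.start, iv.end)]]
    order = rng.permutation(len(candidates))
    patients = sorted(samples_by_patient)
    events: list[PlantedEvent] = []
    used_genes: set[str] = set()
    for idx in order:
        if len(events) == n_events:
            break
        enh = candidates[idx]
        enh_key = (enh.chrom, enh.start, enh.end)
        gene_id = gene_map[enh_key][0][0]
        if gene_id in used_genes:
            continue
        used_genes.add(gene_id)
        chosen_patients = [
            patients[i] for i in
            rng.choice(len(patients), size=min(n_patients_wanted, len(patients)),
                       replace=False)
        ]
        # distribute the mutant samples over the chosen patients, >= 1 each
        alloc = np.ones(len(chosen_patients), dtype=int)
        extra = max(0, n_samples - len(chosen_patients))
        for _ in range(extra):
            alloc[int(rng.integers(0, len(alloc)))] += 1
        mutant_samples: list[str] = []
        for patient, k in zip(chosen_patients, alloc):
            samples = samples_by_patient[patient]
            k = min(k, len(samples))
            picked = [samples[i] for i in
                      rng.choice(len(samples), size=k, replace=False)]
            mutant_samples.extend(picked)
            span = enh_spans[enh_key][int(rng.integers(0, len(enh_spans[enh_key])))]
            overlap_lo = max(span.start, enh.start)
            overlap_hi = min(span.end, enh.end)
            while True:
                pos0 = int(rng.integers(overlap_lo, overlap_hi))
                if (patient, span.chrom, pos0 + 1) not in used_positions:
                    break
            used_positions.add((patient, span.chrom, pos0 + 1))
            if genome.sequences is not None:
                ref = genome.sequences[span.chrom][pos0]
            else:
                ref = "C"
            alt = {"A": "T", "C": "A", "G": "C", "T": "G"}[ref]
            key = emit_variant(patient, span.chrom, pos0 + 1, ref, alt, picked)
            somatic_keys.add(key)
            assignments[key] = frozenset(picked)
            labels[key] = "enhancer"
        events.append(
            PlantedEvent(gene_id=gene_id, enhancer=enh,
                         mutant_samples=tuple(sorted(mutant_samples)),
                         log2_shift=shift)
        )
    if len(events) < n_events:
        raise ValueError("could not plant the requested number of events")
    return events


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    genome: SyntheticGenome,
    truth: CohortTruth,
    baseline_mean: float = 5.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Log2 expression matrix (genes x samples): baseline plus Gaussian
    noise, with each planted event's shift added to its gene in the
    event's mutant samples."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genome.genes]
    samples = truth.all_samples
    values = baseline_mean + rng.normal(0.0, noise_sd,
                                        size=(len(gene_ids), len(samples)))
    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                        columns=samples)
    for event in truth.planted_enhancer_events:
        if event.gene_id not in expr.index:
            raise ValueError(f"planted gene {event.gene_id} absent from genome")
        expr.loc[event.gene_id, list(event.mutant_samples)] += event.log2_shift
    return expr
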