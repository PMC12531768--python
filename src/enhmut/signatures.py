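"""Single-base-substitution (SBS) signature analysis.

Mutation spectra are summarized over the standard 96 trinucleotide
channels: six pyrimidine-centered substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 16 flanking-base contexts,
ordered alphabetically by (5' base, 3' base).  Substitutions whose
reference base is a purine are reverse-complemented onto the
pyrimidine-centered channel (e.g. A[G>T]A counts as T[C>A]T).

Exposures are obtained by *refitting*: the observed spectrum, normalized to
a probability vector, is decomposed over a fixed signature catalog by
non-negative least squares and the weights renormalized to sum to 1.  This
mirrors how per-sample proportions of named COSMIC signatures are usually
reported; de novo extraction (NMF) is deliberately not implemented.

The module also carries the comparative statistics used downstream of the
exposures: Friedman rank tests across region classes blocked by sample,
paired Wilcoxon signed-rank tests between groups, the two-stage adaptive
Benjamini-Krieger-Yekutieli FDR procedure, and a centered PCA of exposure
profiles.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .io_formats import MutationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SBS96_CHANNELS",
    "SUBSTITUTIONS",
    "channel_index",
    "trinucleotide_spectrum",
    "ExposureProfile",
    "fit_exposures",
    "subsample_spectrum",
    "synthetic_catalog",
    "compare_regions_friedman",
    "paired_signed_rank",
    "bky_fdr",
    "pca_exposures",
    "cluster_exposures",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Channel labels in canonical order: substitution class major, then 5' and
#: 3' flanking bases alphabetically.
SBS96_CHANNELS: list[str] = [
    f"{l}[{sub}]{r}" for sub in SUBSTITUTIONS for l in _BASES for r in _BASES
]


def channel_index(ref: str, alt: str, left: str, right: str) -> int:
    """Index (0-95) of the pyrimidine-centered channel for a substitution
    ``ref>alt`` with flanking bases ``left``/``right`` on the reference
    forward strand."""
    if ref in "CT":
        sub = f"{ref}>{alt}"
        l, r = left, right
    else:
        sub = f"{_COMP[ref]}>{_COMP[alt]}"
        l, r = _COMP[right], _COMP[left]
    if sub not in SUBSTITUTIONS:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    return (
        SUBSTITUTIONS.index(sub) * 16 + _BASES.index(l) * 4 + _BASES.index(r)
    )


def trinucleotide_spectrum(
    snvs: Sequence[MutationRecord], reference: dict[str, str]
) -> np.ndarray:
    """96-channel spectrum of single-nucleotide substitutions.

    Indels and multi-nucleotide records are skipped with a logged count, as
    are substitutions at the first/last base of a chromosome (no flanking
    context).  A mismatch between a record's ref allele and the reference
    sequence raises, listing the offending records.
    """
    spectrum = np.zeros(96, dtype=np.int64)
    skipped_non_snv = 0
    skipped_edge = 0
    mismatches: list[str] = []
    for r in snvs:
        if not r.is_snv:
            skipped_non_snv += 1
            continue
        try:
            seq = reference[r.chrom]
        except KeyError:
            raise KeyError(f"chromosome {r.chrom} absent from reference") from None
        pos0 = r.pos - 1
        ref_base = seq[pos0]
        if ref_base != r.ref:
            mismatches.append(
                f"{r.chrom}:{r.pos} table ref={r.ref} reference={ref_base}"
            )
            continue
        if pos0 == 0 or pos0 == len(seq) - 1:
            skipped_edge += 1
            continue
        spectrum[channel_index(r.ref, r.alt, seq[pos0 - 1], seq[pos0 + 1])] += 1
    if mismatches:
        shown = "; ".join(mismatches[:10])
        raise ValueError(
            f"{len(mismatches)} record(s) disagree with the reference: {shown}"
        )
    if skipped_non_snv:
        logger.info("trinucleotide_spectrum: skipped %d non-SNV record(s)",
                    skipped_non_snv)
    if skipped_edge:
        logger.info("trinucleotide_spectrum: skipped %d chromosome-edge SNV(s)",
                    skipped_edge)
    return spectrum


# ---------------------------------------------------------------------------
# exposure refitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExposureProfile:
    """Nonnegative signature weights (summing to 1) reconstructing one
    spectrum, with the NNLS residual norm as reconstruction error."""

    weights: pd.Series
    n_mutations: int
    reconstruction_error: float
    sample_id: str | None = None
    region_label: str | None = None


def fit_exposures(
    spectrum: np.ndarray,
    catalog: pd.DataFrame,
    sample_id: str | None = None,
    region_label: str | None = None,
) -> ExposureProfile:
    """Refit a spectrum against a fixed catalog by non-negative least
    squares on the normalized spectrum, then renormalize weights to sum
    to 1."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (96,):
        raise ValueError(f"expected a 96-channel spectrum, got {spectrum.shape}")
    total = spectrum.sum()
    if total <= 0:
        raise ValueError("cannot fit exposures for an all-zero spectrum")
    target = spectrum / total
    design = catalog.to_numpy(dtype=float)
    w, residual = nnls(design, target)
    weights = pd.Series(w / w.sum() if w.sum() > 0 else w, index=catalog.columns)
    return ExposureProfile(
        weights=weights,
        n_mutations=int(total),
        reconstruction_error=float(residual),
        sample_id=sample_id,
        region_label=region_label,
    )


def subsample_spectrum(
    snvs: Sequence[MutationRecord],
    reference: dict[str, str],
    n: int,
    seed: int,
    zero_ok: bool = False,
) -> np.ndarray:
    """Spectrum of ``n`` mutations sampled uniformly without replacement.

    Used to compare region classes at matched mutation counts (e.g.
    downsampling every class to the coding count).  Deterministic given
    ``seed``.
    """
    if n > len(snvs):
        raise ValueError(f"cannot subsample {n} of {len(snvs)} mutations")
    if n == 0 and not zero_ok:
        raise ValueError("subsample size 0 (pass zero_ok=True for a zero spectrum)")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(snvs), size=n, replace=False)
    return trinucleotide_spectrum([snvs[i] for i in idx], reference)


# ---------------------------------------------------------------------------
# synthetic signature catalog
# ---------------------------------------------------------------------------

def _signature_vector(
    sub_weights: dict[str, float],
    context_tilts: dict[str, tuple[str, str, float]] | None = None,
) -> np.ndarray:
    """Probability vector from per-substitution-class mass and optional
    flank tilts ``{sub: (which_flank, base, fold)}``."""
    vec = np.zeros(96)
    for si, sub in enumerate(SUBSTITUTIONS):
        mass = sub_weights.get(sub, 0.0)
        if mass == 0:
            continue
        ctx = np.ones(16)
        if context_tilts and sub in context_tilts:
            which, base, fold = context_tilts[sub]
            for li, l in enumerate(_BASES):
                for ri, r in enumerate(_BASES):
                    flank = l if which == "5'" else r
                    if flank == base:
                        ctx[li * 4 + ri] *= fold
        vec[si * 16:(si + 1) * 16] = mass * ctx / ctx.sum()
    return vec / vec.sum()


def synthetic_catalog(extra: pd.DataFrame | None = None) -> pd.DataFrame:
    """Synthetic stand-in SBS catalog.

    Columns carry the names of the signatures discussed in the analyses
    this package supports (SBS1, SBS5, SBS8, SBS18, SBS39, SBS40, SBS41),
    but the probability vectors are synthetic constructions — each shaped
    to echo its namesake's dominant substitution class (SBS1: C>T at CpG;
    SBS18: C>A; SBS39: C>G; SBS41: T>A; SBS5/SBS40: flat-ish) — not COSMIC
    reference data.  They are deterministic, mutually well separated, and
    sufficient for refitting and recovery experiments.
    """
    cols = {
        "SBS1": _signature_vector(
            {"C>T": 0.90, "C>A": 0.02, "C>G": 0.02, "T>A": 0.02, "T>C": 0.02,
             "T>G": 0.02},
            {"C>T": ("3'", "G", 12.0)},
        ),
        "SBS5": _signature_vector(
            {"C>A": 0.12, "C>G": 0.08, "C>T": 0.25, "T>A": 0.10, "T>C": 0.30,
             "T>G": 0.15},
        ),
        "SBS8": _signature_vector(
            {"C>A": 0.55, "C>T": 0.25, "C>G": 0.05, "T>A": 0.05, "T>C": 0.05,
             "T>G": 0.05},
            {"C>A": ("5'", "A", 3.0)},
        ),
        "SBS18": _signature_vector(
            {"C>A": 0.85, "C>G": 0.03, "C>T": 0.03, "T>A": 0.03, "T>C": 0.03,
             "T>G": 0.03},
            {"C>A": ("3'", "T", 4.0)},
        ),
        "SBS39": _signature_vector(
            {"C>G": 0.70, "C>T": 0.10, "T>A": 0.05, "C>A": 0.05, "T>C": 0.05,
             "T>G": 0.05},
            {"C>G": ("5'", "T", 3.0)},
        ),
        "SBS40": _signature_vector(
            {"C>A": 0.20, "C>G": 0.10, "C>T": 0.18, "T>A": 0.12, "T>C": 0.22,
             "T>G": 0.18},
            {"T>C": ("5'", "T", 1.8), "C>A": ("3'", "A", 1.8)},
        ),
        "SBS41": _signature_vector(
            {"T>A": 0.70, "T>C": 0.10, "C>A": 0.05, "C>G": 0.05, "C>T": 0.05,
             "T>G": 0.05},
            {"T>A": ("3'", "C", 3.0)},
        ),
    }
    catalog = pd.DataFrame(cols, index=SBS96_CHANNELS)
    if extra is not None:
        catalog = pd.concat([catalog, extra], axis=1)
    return catalog


# ---------------------------------------------------------------------------
# comparative statistics
# ---------------------------------------------------------------------------

def compare_regions_friedman(table: pd.DataFrame) -> tuple[float, float]:
    """Friedman rank test of one signature's weight across region classes
    (columns), blocked by sample (rows).

    Degenerate inputs where every sample has identical weights across all
    regions return ``(0.0, 1.0)`` (no variation to rank).
    """
    if table.isna().any().any():
        raise ValueError("exposure table has missing block entries")
    if table.shape[1] < 3:
        raise ValueError("Friedman test needs at least 3 region columns")
    values = table.to_numpy(dtype=float)
    if np.all(values == values[:, [0]]):
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*[values[:, j] for j in range(values.shape[1])])
    return float(stat), float(p)


def paired_signed_rank(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-sample values.

    Zero differences are dropped (Wilcoxon convention); if all differences
    are zero the test is vacuous and returns ``(0.0, 1.0)``.  Exact null
    distribution for n <= 25 informative pairs, normal approximation with
    continuity correction above.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired groups must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(d, correction=(method == "approx"), method=method)
    return float(res.statistic), float(res.pvalue)


def bky_fdr(pvalues: Sequence[float], q: float = 0.05) -> list[int]:
    """Indices rejected by the two-stage adaptive step-up FDR procedure of
    Benjamini, Krieger & Yekutieli (2006).

    Stage 1 runs Benjamini-Hochberg at q' = q/(1+q) to estimate the number
    of true nulls m0 = m - r1; stage 2 reruns BH at q'* m / m0.  Controls
    the FDR at level q for independent p-values.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_tsbky", maxiter=1)
    return sorted(np.flatnonzero(reject).tolist())


def pca_exposures(
    exposure_matrix: pd.DataFrame | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered (unscaled) PCA of a samples-by-signatures exposure matrix.

    Returns ``(coordinates, explained_variance_ratio, loadings)``.  Signs
    are fixed by making the largest-magnitude entry of each loading vector
    positive.  A constant matrix yields all-zero coordinates and ratios.
    """
    X = np.asarray(exposure_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U * S
    var = S**2 / (X.shape[0] - 1)
    total = var.sum()
    ratios = var / total if total > 0 else np.zeros_like(var)
    return coords, ratios, Vt


def cluster_exposures(exposure_matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Average-linkage hierarchical clustering (Euclidean) of exposure
    profiles; returns the scipy linkage matrix.  A reporting aid only."""
    X = np.asarray(exposure_matrix, dtype=float)
    return linkage(X, method="average", metric="euclidean")
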