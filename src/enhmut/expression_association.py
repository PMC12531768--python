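"""Mutation-expression association screen with permutation-adjusted P.

For each gene assigned to a mutated conserved enhancer, expression of
samples carrying an enhancer mutation is compared with expression of
wild-type samples by a two-sample Wilcoxon rank-sum (Mann-Whitney) test.
Samples with a nonsynonymous coding mutation in the gene are removed first
(a coding hit could alter transcript abundance on its own), and only
samples with both mutation and expression data enter the comparison.

The raw P is then calibrated against a permutation null: the mutant labels
are reshuffled uniformly over the eligible samples (preserving the mutant
count), the test recomputed, and the adjusted P is the proportion of the B
reference P values strictly smaller than the observed one (B = 10,000 by
default).  An exhaustive enumerator over all C(n, k) assignments is
provided for small instances.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conserved_recurrence import UNASSIGNED, RecurrenceTable

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "eligible_samples",
    "ranksum_p",
    "association_test",
    "permutation_adjust",
    "exhaustive_permutation_adjust",
    "run_association_screen",
    "results_to_frame",
]

# beyond this pooled size (or with ties) the exact rank-sum null is replaced
# by the tie-corrected normal approximation with continuity correction
_EXACT_LIMIT = 30


@dataclasses.dataclass
class AssociationResult:
    gene_id: str
    n_mutant: int
    n_wildtype: int
    direction: str  # {up, down, none}
    raw_p: float
    adjusted_p: float
    median_log2_shift: float
    significant: bool


def eligible_samples(
    gene: str,
    expression: pd.DataFrame,
    coding_mutants: set[str] | Sequence[str],
    matched_samples: Sequence[str] | None = None,
) -> list[str]:
    """Samples usable for the gene's test: expression samples (optionally
    restricted to a WGS-RNA matched set) minus the gene's coding-mutant
    samples.  Sorted for determinism."""
    if gene not in expression.index:
        raise KeyError(f"gene {gene} absent from expression matrix")
    pool = set(expression.columns)
    if matched_samples is not None:
        pool &= set(matched_samples)
    return sorted(pool - set(coding_mutants))


# ---------------------------------------------------------------------------
# rank-sum p-values
# ---------------------------------------------------------------------------

def _use_exact(pooled: np.ndarray) -> bool:
    return len(pooled) <= _EXACT_LIMIT and len(np.unique(pooled)) == len(pooled)


def _asymptotic_p_from_u(
    u: np.ndarray | float, n1: int, n2: int, tie_term: float, n: int
) -> np.ndarray | float:
    """Two-sided tie-corrected normal approximation with continuity
    correction, matching scipy's asymptotic Mann-Whitney p-value."""
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return np.ones_like(np.asarray(u, dtype=float))
    z = (np.abs(np.asarray(u, dtype=float) - mu) - 0.5) / math.sqrt(var)
    return np.minimum(1.0, 2.0 * stats.norm.sf(z))


def ranksum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided two-sample rank-sum P; exact null for small tie-free
    pooled samples, tie-corrected normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if _use_exact(pooled):
        return float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
    ranks = stats.rankdata(pooled)
    u1 = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    return float(_asymptotic_p_from_u(u1, len(x), len(y), tie_term, len(pooled)))


def association_test(
    expr_mutant: Sequence[float], expr_wildtype: Sequence[float]
) -> tuple[float, str, float]:
    """Rank-sum comparison of mutant vs wild-type expression.

    Returns ``(raw_p, direction, median_log2_shift)`` where the shift is
    median(mutant) - median(wildtype) and direction its sign.
    """
    x = np.asarray(expr_mutant, dtype=float)
    y = np.asarray(expr_wildtype, dtype=float)
    p = ranksum_p(x, y)
    shift = float(np.median(x) - np.median(y))
    direction = "up" if shift > 0 else ("down" if shift < 0 else "none")
    return p, direction, shift


# ---------------------------------------------------------------------------
# permutation adjustment
# ---------------------------------------------------------------------------

def _permuted_pvalues(
    values: np.ndarray, mutant_count: int, mutant_index_sets: np.ndarray
) -> np.ndarray:
    """P-values of the rank-sum test for many mutant-label assignments over
    the same pooled expression values, computed with the same routine as
    the observed test (memoized over the rank-sum statistic)."""
    n = len(values)
    k = mutant_count
    ranks = stats.rankdata(values)
    rank_sums = ranks[mutant_index_sets].sum(axis=1)
    u1 = rank_sums - k * (k + 1) / 2.0
    if _use_exact(values):
        # exact regime: few distinct U values; evaluate each once
        pvals = np.empty(len(u1))
        cache: dict[float, float] = {}
        for i, u in enumerate(u1):
            if u not in cache:
                idx = mutant_index_sets[i]
                mask = np.zeros(n, dtype=bool)
                mask[idx] = True
                cache[u] = ranksum_p(values[mask], values[~mask])
            pvals[i] = cache[u]
        return pvals
    _, counts = np.unique(values, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    return np.asarray(_asymptotic_p_from_u(u1, k, n - k, tie_term, n))


def permutation_adjust(
    values: Sequence[float],
    mutant_count: int,
    observed_raw_p: float,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
    estimator: str = "proportion",
) -> float:
    """Permutation-adjusted P for one gene.

    ``values`` are the gene's expression values over the eligible samples;
    ``mutant_count`` labels are reshuffled uniformly B times, the rank-sum
    P recomputed for each draw, and the adjusted P returned as the
    proportion of reference P values strictly below ``observed_raw_p``
    (``estimator="proportion"``, the literal definition) or as
    (k+1)/(B+1) (``estimator="add_one"``, positively biased but never 0).
    Deterministic given the seed.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if mutant_count < 1:
        raise ValueError("mutant_count must be >= 1")
    if n <= mutant_count:
        raise ValueError("need more eligible samples than mutant samples")
    if B <= 0:
        raise ValueError("B must be positive")
    if estimator not in ("proportion", "add_one"):
        raise ValueError(f"unknown estimator {estimator!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # B uniform draws of a mutant set of the observed size
    order = np.argsort(rng.random((B, n)), axis=1)[:, :mutant_count]
    pvals = _permuted_pvalues(values, mutant_count, order)
    k = int((pvals < observed_raw_p).sum())
    if estimator == "add_one":
        return (k + 1) / (B + 1)
    return k / B


def exhaustive_permutation_adjust(
    values: Sequence[float],
    mutant_count: int,
    observed_raw_p: float,
    max_assignments: int = 200_000,
) -> float:
    """Exact version of :func:`permutation_adjust`: the proportion over all
    C(n, k) mutant-label assignments whose rank-sum P is strictly below the
    observed one."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    total = math.comb(n, mutant_count)
    if total > max_assignments:
        raise ValueError(
            f"C({n},{mutant_count}) = {total} assignments exceed the "
            f"enumeration limit {max_assignments}"
        )
    sets = np.array(list(itertools.combinations(range(n), mutant_count)))
    pvals = _permuted_pvalues(values, mutant_count, sets)
    return float((pvals < observed_raw_p).sum() / total)


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def run_association_screen(
    recurrence: RecurrenceTable,
    expression: pd.DataFrame,
    coding_mutants: Mapping[str, set[str]] | None = None,
    alpha: float = 0.05,
    B: int = 10_000,
    seed: int = 0,
    matched_samples: Sequence[str] | None = None,
    estimator: str = "proportion",
) -> list[AssociationResult]:
    """Mutant-vs-wildtype expression test for every testable gene.

    Genes come from the recurrence table (any gene with >= 1 mutated
    sample).  For each gene the mutant set is its enhancer-mutated samples
    restricted to eligible samples; genes with no wild-type (or no mutant)
    eligible samples are skipped with a logged reason.  Results are sorted
    by adjusted P then gene id; ``significant`` means adjusted_p < alpha.
    """
    coding_mutants = coding_mutants or {}
    results: list[AssociationResult] = []
    skipped: list[str] = []
    genes = sorted(g for g in recurrence.samples if g != UNASSIGNED)
    seeds = np.random.SeedSequence(seed).spawn(len(genes))
    for gene, gene_seed in zip(genes, seeds):
        if gene not in expression.index:
            skipped.append(f"{gene}: no expression data")
            continue
        eligible = eligible_samples(
            gene, expression, coding_mutants.get(gene, set()), matched_samples
        )
        mutant = sorted(set(recurrence.samples[gene]) & set(eligible))
        wildtype = sorted(set(eligible) - set(mutant))
        if not mutant or not wildtype:
            skipped.append(
                f"{gene}: {len(mutant)} mutant / {len(wildtype)} wild-type "
                "eligible samples"
            )
            continue
        expr = expression.loc[gene]
        x = expr[mutant].to_numpy(dtype=float)
        y = expr[wildtype].to_numpy(dtype=float)
        raw_p, direction, shift = association_test(x, y)
        values = expr[eligible].to_numpy(dtype=float)
        adjusted = permutation_adjust(
            values, len(mutant), raw_p, B=B,
            seed=np.random.default_rng(gene_seed), estimator=estimator,
        )
        results.append(
            AssociationResult(
                gene_id=gene,
                n_mutant=len(mutant),
                n_wildtype=len(wildtype),
                direction=direction,
                raw_p=raw_p,
                adjusted_p=adjusted,
                median_log2_shift=shift,
                significant=adjusted < alpha,
            )
        )
    if skipped:
        logger.info("association screen skipped %d gene(s): %s",
                    len(skipped), "; ".join(skipped[:10]))
    results.sort(key=lambda r: (r.adjusted_p, r.gene_id))
    return results


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    cols = ["gene_id", "n_mutant", "n_wildtype", "direction", "raw_p",
            "adjusted_p", "median_log2_shift", "significant"]
    return pd.DataFrame([dataclasses.asdict(r) for r in results], columns=cols)
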