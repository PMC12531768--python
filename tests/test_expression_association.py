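"""Rank-sum association test and permutation-based P adjustment, checked
against exhaustive assignment enumeration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enhmut.conserved_recurrence import RecurrenceTable
from enhmut.expression_association import (
    association_test,
    eligible_samples,
    exhaustive_permutation_adjust,
    permutation_adjust,
    ranksum_p,
    results_to_frame,
    run_association_screen,
)


class TestEligibleSamples:
    EXPR = pd.DataFrame(
        np.zeros((1, 10)),
        index=["g1"],
        columns=[f"s{i}" for i in range(10)],
    )

    def test_set_subtraction(self):
        out = eligible_samples("g1", self.EXPR, {"s0", "s3"})
        assert out == sorted(set(self.EXPR.columns) - {"s0", "s3"})

    def test_all_coding_mutant_empty(self):
        assert eligible_samples("g1", self.EXPR, set(self.EXPR.columns)) == []

    def test_matched_restriction(self):
        out = eligible_samples("g1", self.EXPR, {"s0"}, matched_samples=["s0",
                                                                         "s1"])
        assert out == ["s1"]

    def test_absent_gene_raises(self):
        with pytest.raises(KeyError, match="g2"):
            eligible_samples("g2", self.EXPR, set())


class TestAssociationTest:
    def test_identical_groups(self):
        p, direction, shift = association_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0 and shift == 0.0 and direction == "none"

    def test_fully_separated_small_groups(self):
        p, direction, shift = association_test([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)
        assert direction == "down" and shift == -9.0

    def test_monotone_transform_leaves_p_unchanged(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=7), rng.normal(size=9) + 0.5
        p1, *_ = association_test(x, y)
        p2, *_ = association_test(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            association_test([], [1.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_in_asymptotic_regime(self, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(size=25), 1)
        y = np.round(rng.normal(size=20), 1)
        want = stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic",
                                  use_continuity=True).pvalue
        assert ranksum_p(x, y) == pytest.approx(want, abs=1e-12)


class TestPermutationAdjust:
    def test_observed_p_zero_lower_bound(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=12)
        assert permutation_adjust(values, 3, 0.0, B=500, seed=1) == 0.0

    def test_exhaustive_small_instance(self):
        # C(6,2) = 15 assignments: Monte-Carlo converges to the exact
        # proportion as B grows
        values = np.array([0.1, 0.4, 1.2, 2.5, 3.3, 4.1])
        obs_p, *_ = association_test(values[:2], values[2:])
        exact = exhaustive_permutation_adjust(values, 2, obs_p)
        for B, tol in [(100, 0.15), (1_000, 0.05), (10_000, 0.02)]:
            mc = permutation_adjust(values, 2, obs_p, B=B, seed=2)
            assert abs(mc - exact) <= tol

    def test_invalid_arguments(self):
        values = np.arange(6.0)
        with pytest.raises(ValueError, match="B"):
            permutation_adjust(values, 2, 0.5, B=0)
        with pytest.raises(ValueError, match="mutant_count"):
            permutation_adjust(values, 0, 0.5)
        with pytest.raises(ValueError, match="eligible"):
            permutation_adjust(values, 6, 0.5)

    def test_add_one_estimator(self):
        values = np.random.default_rng(5).normal(size=10)
        a = permutation_adjust(values, 3, 0.2, B=200, seed=3)
        b = permutation_adjust(values, 3, 0.2, B=200, seed=3,
                               estimator="add_one")
        assert b == pytest.approx((a * 200 + 1) / 201)

    def test_deterministic_given_seed(self):
        values = np.random.default_rng(6).normal(size=40)
        a = permutation_adjust(values, 4, 0.1, B=2_000, seed=9)
        b = permutation_adjust(values, 4, 0.1, B=2_000, seed=9)
        assert a == b


class TestScreen:
    def _inputs(self, shift=-3.0, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(24)]
        genes = ["hit"] + [f"null{i}" for i in range(5)]
        expr = pd.DataFrame(rng.normal(5, 0.5, size=(len(genes), 24)),
                            index=genes, columns=samples)
        mutant = {"hit": {"s0", "s1", "s2", "s3"}}
        for g in genes[1:]:
            mutant[g] = set(rng.choice(samples, size=3, replace=False))
        expr.loc["hit", sorted(mutant["hit"])] += shift
        table = RecurrenceTable(samples=mutant,
                                patients={g: {s[:2] for s in m}
                                          for g, m in mutant.items()})
        return table, expr

    def test_planted_gene_detected_nulls_at_nominal_rate(self):
        table, expr = self._inputs()
        results = run_association_screen(table, expr, B=2_000, seed=7)
        sig = [r.gene_id for r in results if r.significant]
        assert "hit" in sig
        # null genes reach significance at the nominal 5% rate at most;
        # with 5 nulls more than one hit would be a >3-sigma excess
        assert sum(1 for g in sig if g != "hit") <= 1
        hit = results[0]
        assert hit.gene_id == "hit" and hit.direction == "down"
        assert hit.adjusted_p <= 0.01
        assert hit.n_mutant == 4 and hit.n_wildtype == 20

    def test_alpha_zero_nothing_significant(self):
        table, expr = self._inputs()
        results = run_association_screen(table, expr, alpha=0.0, B=500, seed=7)
        assert not any(r.significant for r in results)

    def test_sample_order_invariance(self):
        table, expr = self._inputs()
        shuffled = expr[list(reversed(expr.columns))]
        a = results_to_frame(run_association_screen(table, expr, B=1_000,
                                                    seed=3))
        b = results_to_frame(run_association_screen(table, shuffled, B=1_000,
                                                    seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_coding_mutants_excluded(self):
        table, expr = self._inputs()
        coding = {"hit": {"s5", "s6"}}
        results = run_association_screen(table, expr, coding_mutants=coding,
                                         B=500, seed=7)
        hit = next(r for r in results if r.gene_id == "hit")
        assert hit.n_mutant + hit.n_wildtype == 22

    def test_untestable_gene_skipped(self):
        table, expr = self._inputs()
        # make every sample a coding mutant for one null gene
        coding = {"null0": set(expr.columns)}
        results = run_association_screen(table, expr, coding_mutants=coding,
                                         B=500, seed=7)
        assert "null0" not in {r.gene_id for r in results}

    def test_null_raw_p_roughly_uniform(self):
        rng = np.random.default_rng(12)
        samples = [f"s{i}" for i in range(30)]
        genes = [f"n{i}" for i in range(300)]
        expr = pd.DataFrame(rng.normal(size=(300, 30)), index=genes,
                            columns=samples)
        mutant = {g: set(rng.choice(samples, size=3, replace=False))
                  for g in genes}
        table = RecurrenceTable(samples=mutant, patients=mutant)
        results = run_association_screen(table, expr, B=200, seed=13)
        raw = np.array([r.raw_p for r in results])
        assert abs(raw.mean() - 0.5) < 0.06
        assert (raw < 0.1).mean() < 0.2


def test_cohort_screen_recovers_planted_genes(genome, cohort, expression):
    """Planted ~10-fold expression drops are the significant hits of the
    full simulated screen."""
    import enhmut as em
    from enhmut.conserved_recurrence import (
        build_enhancer_gene_map, enhancer_mutation_table, recurrence_table,
    )
    from enhmut.io_formats import frame_to_records

    table, truth = cohort
    passing, _ = em.filter_cohort(frame_to_records(table))
    present = table[table.t_alt >= 1]
    keys = list(zip(present.patient_id, present.chrom, present.pos,
                    present.ref, present.alt))
    df = present[[k in passing for k in keys]]
    annotated = enhancer_mutation_table(df, genome.enhancers,
                                        genome.conserved_flags)
    conserved = [iv for iv, f in zip(genome.enhancers, genome.conserved_flags)
                 if f]
    rec = recurrence_table(annotated, build_enhancer_gene_map(conserved,
                                                              genome.genes))
    results = run_association_screen(rec, expression,
                                     truth.coding_mutant_samples,
                                     B=2_000, seed=21)
    sig = {r.gene_id for r in results if r.significant}
    planted = {e.gene_id for e in truth.planted_enhancer_events}
    assert planted <= sig
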