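"""Spectrum construction, exposure refitting and the comparative
statistics, each checked against an independent enumeration or direct
formula oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enhmut.io_formats import MutationRecord
from enhmut.signatures import (
    SBS96_CHANNELS,
    bky_fdr,
    channel_index,
    compare_regions_friedman,
    fit_exposures,
    paired_signed_rank,
    pca_exposures,
    subsample_spectrum,
    synthetic_catalog,
    trinucleotide_spectrum,
)


def _snv(pos, ref, alt, chrom="chr1"):
    return MutationRecord("P", "S", chrom, pos, ref, alt, 60, 20, 40, 0)


class TestSpectrum:
    def test_purine_reference_reverse_complemented(self):
        # A[G>T]A on the forward strand is the T[C>A]T channel
        ref = {"chr1": "AAGAA"}
        spectrum = trinucleotide_spectrum([_snv(3, "G", "T")], ref)
        assert spectrum.sum() == 1
        assert spectrum[SBS96_CHANNELS.index("T[C>A]T")] == 1

    def test_pyrimidine_reference_direct(self):
        ref = {"chr1": "ACTGA"}
        spectrum = trinucleotide_spectrum([_snv(3, "T", "C")], ref)
        assert spectrum[SBS96_CHANNELS.index("C[T>C]G")] == 1

    def test_empty_input_all_zero(self):
        assert trinucleotide_spectrum([], {"chr1": "ACGT"}).sum() == 0

    def test_reference_mismatch_raises(self):
        with pytest.raises(ValueError, match="disagree"):
            trinucleotide_spectrum([_snv(3, "C", "T")], {"chr1": "AAGAA"})

    def test_indels_skipped_with_count_preserved(self):
        ref = {"chr1": "AACAA"}
        records = [_snv(3, "C", "T"),
                   MutationRecord("P", "S", "chr1", 3, "CA", "C", 60, 20, 40, 0)]
        spectrum = trinucleotide_spectrum(records, ref)
        assert spectrum.sum() == 1

    def test_channel_index_covers_all_96(self):
        seen = set()
        for ref in "CT":
            for alt in "ACGT":
                if alt == ref:
                    continue
                for l in "ACGT":
                    for r in "ACGT":
                        seen.add(channel_index(ref, alt, l, r))
        assert seen == set(range(96))


class TestFitExposures:
    def test_exact_catalog_member(self):
        cat = synthetic_catalog()
        spectrum = np.round(cat["SBS18"].to_numpy() * 50_000)
        prof = fit_exposures(spectrum, cat)
        assert prof.weights["SBS18"] > 0.98
        assert prof.reconstruction_error < 0.01

    def test_single_signature_catalog_normalizes_to_one(self):
        cat = synthetic_catalog()[["SBS5"]]
        spectrum = np.ones(96)
        prof = fit_exposures(spectrum, cat)
        assert prof.weights.sum() == pytest.approx(1.0)

    def test_all_zero_spectrum_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_exposures(np.zeros(96), synthetic_catalog())

    def test_mixture_recovery(self):
        cat = synthetic_catalog()[["SBS1", "SBS18", "SBS39"]]
        truth = np.array([0.6, 0.3, 0.1])
        rng = np.random.default_rng(41)
        channels = rng.choice(96, size=2_000, p=cat.to_numpy() @ truth)
        spectrum = np.bincount(channels, minlength=96)
        prof = fit_exposures(spectrum, cat)
        np.testing.assert_allclose(prof.weights.to_numpy(), truth, atol=0.05)

    def test_reconstruction_never_worse_than_best_single(self):
        cat = synthetic_catalog()
        rng = np.random.default_rng(42)
        spectrum = rng.poisson(20, size=96).astype(float)
        prof = fit_exposures(spectrum, cat)
        target = spectrum / spectrum.sum()
        singles = [
            np.linalg.norm(target - cat[c].to_numpy()
                           * (target @ cat[c].to_numpy())
                           / (cat[c].to_numpy() @ cat[c].to_numpy()))
            for c in cat.columns
        ]
        assert prof.reconstruction_error <= min(singles) + 1e-12


class TestSubsample:
    REF = {"chr1": "A" + "ACGT" * 30 + "A"}

    def _records(self):
        out = []
        for i, base in enumerate(self.REF["chr1"][1:-1], start=2):
            if base in "CT":
                out.append(_snv(i, base, "A" if base != "A" else "G"))
        return out

    def test_full_subsample_identical(self):
        recs = self._records()
        full = trinucleotide_spectrum(recs, self.REF)
        sub = subsample_spectrum(recs, self.REF, len(recs), seed=1)
        np.testing.assert_array_equal(full, sub)

    def test_zero_default_error(self):
        with pytest.raises(ValueError, match="0"):
            subsample_spectrum(self._records(), self.REF, 0, seed=1)

    def test_oversample_error(self):
        recs = self._records()
        with pytest.raises(ValueError, match="subsample"):
            subsample_spectrum(recs, self.REF, len(recs) + 1, seed=1)

    def test_deterministic(self):
        recs = self._records()
        a = subsample_spectrum(recs, self.REF, 10, seed=7)
        b = subsample_spectrum(recs, self.REF, 10, seed=7)
        np.testing.assert_array_equal(a, b)


def _friedman_direct(X):
    """Direct rank formula with tie correction (chi-square null)."""
    n, k = X.shape
    R = np.apply_along_axis(stats.rankdata, 1, X)
    A = (R**2).sum()
    C = n * k * (k + 1) ** 2 / 4
    stat = (k - 1) * ((R.sum(axis=0) ** 2).sum() - n**2 * k * (k + 1) ** 2 / 4) \
        / (A - C)
    return stat, stats.chi2.sf(stat, k - 1)


class TestFriedman:
    def test_constant_rows_give_p_one(self):
        table = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        assert compare_regions_friedman(table) == (0.0, 1.0)

    def test_uniformly_highest_region_minimal_p(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 4))
        X[:, 2] += 100  # one region always ranked top
        stat, p = compare_regions_friedman(pd.DataFrame(X))
        want_stat, want_p = _friedman_direct(X)
        assert p == pytest.approx(want_p, abs=1e-9)
        assert stat == pytest.approx(want_stat, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        X = np.round(rng.normal(size=(6, 4)), 1)  # rounded -> some ties
        stat, p = compare_regions_friedman(pd.DataFrame(X))
        want_stat, want_p = _friedman_direct(X)
        assert stat == pytest.approx(want_stat, abs=1e-9)
        assert p == pytest.approx(want_p, abs=1e-9)

    def test_missing_entry_raises(self):
        table = pd.DataFrame(np.ones((4, 4)))
        table.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            compare_regions_friedman(table)


def _signed_rank_enumeration(d):
    """Exact two-sided P by enumerating all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    r = stats.rankdata(np.abs(d))
    t_obs = r[d > 0].sum()
    ts = np.array([
        r[np.array(signs, dtype=bool)].sum()
        for signs in itertools.product([0, 1], repeat=len(d))
    ])
    return min(1.0, 2 * min((ts <= t_obs).mean(), (ts >= t_obs).mean()))


class TestSignedRank:
    def test_identical_groups_p_one(self):
        assert paired_signed_rank([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_six_positive_differences(self):
        _, p = paired_signed_rank([2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6])
        assert p == pytest.approx(2 / 64)

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(2, 9))
        perm = rng.permutation(9)
        assert paired_signed_rank(a, b)[1] == paired_signed_rank(a[perm],
                                                                 b[perm])[1]

    @pytest.mark.parametrize("seed", [10, 11, 12, 13, 14])
    def test_matches_sign_flip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        _, p = paired_signed_rank(a, b)
        assert p == pytest.approx(_signed_rank_enumeration(a - b), abs=1e-9)


class TestBkyFdr:
    def test_all_ones_no_rejection(self):
        assert bky_fdr([1.0] * 20) == []

    def test_single_small_p_rejected(self):
        assert bky_fdr([0.001]) == [0]

    def test_empty_input(self):
        assert bky_fdr([]) == []

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bky_fdr([0.5, 1.2])

    def test_superset_of_bh_when_null_fraction_small(self):
        # stage-2 level q' * m / m0 exceeds q whenever m0 <= m/(1+q)
        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(size=50),
                            rng.beta(1, 200, size=60)])
        q = 0.05
        bky = set(bky_fdr(p, q))
        from statsmodels.stats.multitest import multipletests
        bh = set(np.flatnonzero(multipletests(p, alpha=q,
                                              method="fdr_bh")[0]))
        m = len(p)
        m0 = m - len(set(np.flatnonzero(
            multipletests(p, alpha=q / (1 + q), method="fdr_bh")[0])))
        if m0 <= m / (1 + q):
            assert bh <= bky

    def test_fdr_controlled_on_mixture(self):
        # quick version of the calibration experiment (full one in the
        # acceptance suite)
        rng = np.random.default_rng(9)
        fdp = []
        for _ in range(100):
            nulls = rng.uniform(size=400)
            signals = rng.beta(1, 50, size=20)
            p = np.concatenate([nulls, signals])
            rej = bky_fdr(p, 0.05)
            if rej:
                v = sum(1 for i in rej if i < 400)
                fdp.append(v / len(rej))
            else:
                fdp.append(0.0)
        mcse = np.std(fdp) / np.sqrt(len(fdp))
        assert np.mean(fdp) <= 0.05 + 2 * mcse


class TestPca:
    def test_duplicated_rows_identical_coordinates(self):
        X = np.array([[1.0, 2.0, 3.0], [4.0, 0.0, 1.0], [1.0, 2.0, 3.0]])
        coords, _, _ = pca_exposures(X)
        np.testing.assert_allclose(coords[0], coords[2], atol=1e-12)

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(6)
        _, ratios, _ = pca_exposures(rng.normal(size=(10, 4)))
        assert ratios.sum() == pytest.approx(1.0)

    def test_rank_one_structure(self):
        rng = np.random.default_rng(7)
        t = rng.normal(size=12)
        X = np.outer(t, [0.6, -0.8]) + rng.normal(scale=1e-6, size=(12, 2))
        _, ratios, _ = pca_exposures(X)
        assert ratios[0] > 0.99

    def test_constant_matrix_zero_variance(self):
        coords, ratios, _ = pca_exposures(np.ones((5, 3)))
        np.testing.assert_allclose(coords, 0.0, atol=1e-12)
        np.testing.assert_allclose(ratios, 0.0)

    def test_largest_loading_entry_positive(self):
        rng = np.random.default_rng(8)
        _, _, loadings = pca_exposures(rng.normal(size=(15, 5)))
        for row in loadings:
            assert row[np.argmax(np.abs(row))] > 0
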