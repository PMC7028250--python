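"""Permutation schemes, correlation tests, FDR, NBS, regression fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diurnalfmri import (between_participant_corr, build_permutation_scheme,
                         fdr_correct, fit_lines, network_based_statistic,
                         paired_run_test, perm_pvalue, regress_covariate,
                         within_participant_corr)

from _oracles import brute_bh, brute_components, enumerate_family_permutations


class TestPermutationScheme:
    def test_three_family_enumeration_has_eight_permutations(self):
        fams = ["A", "A", "B", "B", "C"]
        scheme = build_permutation_scheme(fams, seed=0)
        drawn = {tuple(p) for p in scheme.draw_matrix(3000)}
        expected = enumerate_family_permutations(fams)
        assert len(expected) == 8
        assert drawn == expected

    def test_singleton_families_are_unrestricted(self):
        fams = ["A", "B", "C"]
        scheme = build_permutation_scheme(fams, seed=1)
        drawn = {tuple(p) for p in scheme.draw_matrix(2000)}
        assert len(drawn) == 6  # all 3! permutations reachable

    def test_all_draws_preserve_family_partition(self):
        fams = ["A", "A", "A", "B", "B", "C", "C", "D"]
        scheme = build_permutation_scheme(fams, seed=2)
        for perm in scheme.draw_matrix(500):
            assert scheme.is_valid_permutation(perm)
            assert sorted(perm) == list(range(8))

    def test_same_seed_identical_stream(self):
        fams = ["A", "A", "B", "B", "C"]
        s1 = build_permutation_scheme(fams, seed=3).draw_matrix(50)
        s2 = build_permutation_scheme(fams, seed=3).draw_matrix(50)
        assert np.array_equal(s1, s2)


class TestPermPvalue:
    def test_extreme_observation(self, rng):
        nulls = rng.normal(0, 1, 999)
        obs = np.abs(nulls).max() + 1.0
        assert perm_pvalue(obs, nulls) == pytest.approx(1.0 / 1000.0)

    def test_zero_observation_near_one(self, rng):
        nulls = rng.normal(0, 1, 999)
        assert perm_pvalue(0.0, nulls) > 0.99

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_observation(self, a, b):
        nulls = np.linspace(-2, 2, 99)
        lo, hi = sorted([a, b])
        assert perm_pvalue(hi, nulls) <= perm_pvalue(lo, nulls)


class TestBetweenCorr:
    def test_perfect_negative(self):
        tod = np.array([9.0, 11.0, 14.0, 18.0, 20.0, 21.0])
        res = between_participant_corr(-tod, tod, ["a"] * 3 + ["b"] * 3,
                                       n_perm=99, seed=0)
        assert res.r == pytest.approx(-1.0)
        assert res.level == "between"

    def test_independent_data_not_significant(self, rng):
        n = 200
        res = between_participant_corr(rng.normal(0, 1, n), rng.normal(12, 2, n),
                                       [f"f{i}" for i in range(n)],
                                       n_perm=499, seed=1)
        assert abs(res.r) < 0.14
        assert res.p > 0.05

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            between_participant_corr(np.ones(10), np.arange(10.0),
                                     [f"f{i}" for i in range(10)])


class TestWithinCorr:
    def test_proportional_deltas(self):
        dt = np.array([-3.0, 1.0, 2.0, 4.0, -1.0])
        res = within_participant_corr(-2.0 * dt, dt, [f"f{i}" for i in range(5)],
                                      n_perm=99, seed=0)
        assert res.r == pytest.approx(-1.0)
        assert res.level == "within"

    def test_constant_delta_tod_errors(self):
        with pytest.raises(ValueError):
            within_participant_corr(np.arange(5.0), np.zeros(5),
                                    [f"f{i}" for i in range(5)])


class TestFDR:
    def test_examples(self):
        reject, _ = fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert reject.all()
        reject, _ = fdr_correct(np.ones(6), q=0.05)
        assert not reject.any()
        reject, _ = fdr_correct(np.array([0.03]), q=0.05)
        assert reject.all()

    def test_agrees_with_brute_force_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(300):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, m)
            ours, _ = fdr_correct(p, q=0.05)
            assert np.array_equal(ours, brute_bh(p, q=0.05))
            sm_reject = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(ours, sm_reject)


class TestRegressCovariate:
    def test_exact_linear_zero_residuals(self):
        x = np.linspace(0, 1, 20)
        assert np.allclose(regress_covariate(3.0 + 2.0 * x, x), 0.0, atol=1e-12)

    def test_residuals_uncorrelated_with_x(self, rng):
        x = rng.normal(0, 1, 100)
        y = 0.5 * x + rng.normal(0, 1, 100)
        resid = regress_covariate(y, x)
        assert abs(np.corrcoef(resid, x)[0, 1]) < 1e-10


class TestPairedRunTest:
    def test_identical_runs(self, rng):
        a = rng.normal(0, 1, 20)
        t, p = paired_run_test(a, a, [f"f{i}" for i in range(20)], n_perm=99)
        assert t == 0.0

    def test_constant_positive_shift(self, rng):
        a = rng.normal(0, 1, 30)
        b = a + 2.0 + rng.normal(0, 0.1, 30)
        t, p = paired_run_test(a, b, [f"f{i}" for i in range(30)],
                               n_perm=499, seed=0)
        assert t > 0
        assert p < 0.05


class TestFitLines:
    def test_exact_linear_all_methods(self):
        x = np.linspace(0, 10, 50)
        y = -0.4 * x + 3.0
        for method in ("ols", "robust_huber", "quantile_median"):
            slope, intercept = fit_lines(y, x, method)
            assert slope == pytest.approx(-0.4, abs=1e-6)
            assert intercept == pytest.approx(3.0, abs=1e-5)

    def test_robust_beats_ols_with_outlier(self, rng):
        x = np.linspace(0, 10, 60)
        y = 1.0 * x + rng.normal(0, 0.2, 60)
        y[5] += 80.0
        ols, _ = fit_lines(y, x, "ols")
        rob, _ = fit_lines(y, x, "robust_huber")
        assert abs(rob - 1.0) < abs(ols - 1.0)

    def test_methods_agree_under_symmetric_noise(self, rng):
        x = rng.uniform(0, 10, 500)
        y = 2.0 * x + rng.normal(0, 1.0, 500)
        slopes = [fit_lines(y, x, m)[0]
                  for m in ("ols", "robust_huber", "quantile_median")]
        assert all(abs(s - 2.0) / 2.0 < 0.1 for s in slopes)


class TestNBS:
    def test_components_match_brute_force(self, rng):
        from diurnalfmri.inference import _components_from_mask
        for _ in range(200):
            R = int(rng.integers(3, 13))
            iu = np.triu_indices(R, 1)
            mask = rng.uniform(size=iu[0].size) < 0.25
            labels, extent, rows, cols = _components_from_mask(mask, iu, R)
            ours = set()
            comp_ids = np.flatnonzero(extent > 0)
            for cid in comp_ids:
                sel = labels[rows] == cid
                ours.add(frozenset(zip(rows[sel].tolist(), cols[sel].tolist())))
            theirs = set(brute_components(list(zip(iu[0][mask], iu[1][mask])), R))
            assert ours == theirs

    def test_empty_suprathreshold_set(self, rng):
        stack = rng.normal(0, 0.02, (30, 6, 6))
        res = network_based_statistic(stack, rng.normal(0, 1, 30),
                                      n_perm=99, seed=0, edge_p_thresh=1e-9)
        assert res.components == []
        assert res.sizes.size == 0

    def test_planted_block_found(self, rng):
        n, R = 100, 12
        cov = rng.normal(0, 1, n)
        stack = rng.normal(0, 0.05, (n, R, R))
        for i in range(4):
            for j in range(4):
                if i != j:
                    stack[:, i, j] += 0.25 * cov
        res = network_based_statistic(stack, cov, n_perm=199, seed=1)
        assert res.sizes.size > 0
        top = res.components[int(np.argmax(res.sizes))]
        assert set(np.unique(top)) >= {0, 1, 2, 3}
        assert res.q_reject[int(np.argmax(res.sizes))]


class TestExchangeabilitySensitivity:
    def test_naive_permutation_inflates_family_confounded_nulls(self):
        """With strong family random effects and a family-level covariate,
        unrestricted permutation is anticonservative; the family scheme
        holds its level."""
        rng = np.random.default_rng(7)
        n_fam, size = 20, 3
        fams = np.repeat([f"f{i}" for i in range(n_fam)], size)
        naive_rej = fam_rej = 0
        n_rep = 150
        for _ in range(n_rep):
            fam_m = np.repeat(rng.normal(0, 1, n_fam), size)
            fam_c = np.repeat(rng.normal(0, 1, n_fam), size)
            metric = fam_m + rng.normal(0, 0.2, n_fam * size)
            cov = fam_c + rng.normal(0, 0.2, n_fam * size)
            zm = (metric - metric.mean()) / metric.std()
            zc = (cov - cov.mean()) / cov.std()
            r = zm @ zc / zm.size
            # naive: unrestricted shuffles
            nulls = [np.corrcoef(rng.permutation(metric), cov)[0, 1]
                     for _ in range(199)]
            if perm_pvalue(r, np.asarray(nulls)) <= 0.05:
                naive_rej += 1
            res = between_participant_corr(metric, cov, fams, n_perm=199,
                                           seed=int(rng.integers(2**31)))
            if res.p <= 0.05:
                fam_rej += 1
        assert naive_rej / n_rep > fam_rej / n_rep + 0.05
        assert fam_rej / n_rep < 0.12
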