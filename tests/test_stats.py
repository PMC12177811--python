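import numpy as np
import pytest
import scipy.stats as sps

from oracles import barnard_brute_p, mannwhitney_exact_p, tfce_brute
from tractcrowd.io_formats import SubjectRecord
from tractcrowd.stats import (
    TFCEParams,
    barnard_exact,
    classify_crowding,
    fit_crowding_models,
    fit_logistic,
    mannwhitney_p,
    mannwhitney_z,
    permutation_fwe,
    tfce_1d,
    tfce_scores,
    whole_tract_compare,
)
from tractcrowd.synthetic_data import simulate_bin_profiles


class TestMannWhitney:
    def test_identical_samples_zero(self):
        assert mannwhitney_z([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_separated_samples(self):
        z = mannwhitney_z([1, 2, 3], [4, 5, 6])
        assert z < 0  # group a stochastically smaller
        assert mannwhitney_p([1, 2, 3], [4, 5, 6], method="exact") == pytest.approx(0.1)

    def test_sign_convention(self):
        assert mannwhitney_z([10, 11, 12], [1, 2, 3]) > 0

    def test_all_tied_zero(self):
        assert mannwhitney_z([5.0, 5.0, 5.0], [5.0, 5.0]) == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_z([1.0], [2.0, 3.0])

    def test_missing_dropped(self):
        z1 = mannwhitney_z([1, 2, np.nan, 3], [4, 5, 6])
        z2 = mannwhitney_z([1, 2, 3], [4, 5, 6])
        assert z1 == z2

    def test_exact_matches_oracle(self, rng):
        for _ in range(25):
            m, n = rng.integers(2, 7, 2)
            a = np.round(rng.normal(size=m), 1)  # rounding induces ties
            b = np.round(rng.normal(size=n), 1)
            assert mannwhitney_p(a, b, method="exact") == pytest.approx(
                mannwhitney_exact_p(a.tolist(), b.tolist())
            )

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            m, n = rng.integers(3, 8, 2)
            a, b = rng.normal(size=m), rng.normal(size=n)
            ours = mannwhitney_p(a, b, method="exact")
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_z_matches_scipy_asymptotic(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=15), rng.normal(size=12)
            p_ref = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert mannwhitney_p(a, b, method="normal") == pytest.approx(float(p_ref))


class TestTFCE:
    def test_zeros(self):
        assert np.allclose(tfce_1d(np.zeros(7)), 0.0)

    def test_single_bin_direct_sum(self):
        got = tfce_1d(np.array([2.0]))[0]
        expected = sum((0.01 * i) ** 2 * 0.01 for i in range(1, 201))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_single_bin_analytic_limit(self):
        got = tfce_1d(np.array([2.0]), TFCEParams(dh=1e-4))[0]
        assert abs(got - 8.0 / 3.0) / (8.0 / 3.0) < 0.01

    def test_matches_brute_oracle(self, rng):
        for _ in range(30):
            z = rng.normal(0, 2, size=7)
            assert np.abs(tfce_scores(z) - np.array(tfce_brute(z))).max() < 1e-9

    def test_monotone_in_z(self, rng):
        for _ in range(50):
            z1 = np.abs(rng.normal(0, 1.5, size=7))
            z2 = z1 + np.abs(rng.normal(0, 0.5, size=7))
            assert np.all(tfce_scores(z2) - tfce_scores(z1) >= -1e-12)

    def test_two_sided_symmetry(self, rng):
        z = rng.normal(0, 2, size=7)
        assert np.allclose(tfce_scores(z), tfce_scores(-z))

    def test_extent_weighting(self):
        # a 3-bin plateau must beat an isolated bin of equal height
        plateau = tfce_scores(np.array([0.0, 2.0, 2.0, 2.0, 0.0]))[2]
        single = tfce_scores(np.array([0.0, 0.0, 2.0, 0.0, 0.0]))[2]
        assert plateau > single


class TestPermutationFWE:
    def test_exhaustive_for_small_groups(self, rng):
        profiles, labels = simulate_bin_profiles(4, 4, rng)
        res = permutation_fwe(profiles, labels, TFCEParams(n_permutations=10000, seed=0))
        assert res.exhaustive
        assert res.n_permutations == 70

    def test_sampled_close_to_exhaustive(self, rng):
        profiles, labels = simulate_bin_profiles(6, 6, rng, effect_bin=4, effect_size_d=1.5)
        exact = permutation_fwe(profiles, labels, TFCEParams(n_permutations=10000, seed=0))
        sampled = permutation_fwe(profiles, labels, TFCEParams(n_permutations=500, seed=1))
        assert not sampled.exhaustive
        assert np.abs(exact.p_corrected - sampled.p_corrected).max() <= 2.0 / np.sqrt(500)

    def test_overwhelming_effect_gives_zero_p(self, rng):
        profiles, labels = simulate_bin_profiles(10, 10, rng, effect_bin=3, effect_size_d=50.0)
        res = permutation_fwe(profiles, labels, TFCEParams(n_permutations=200, seed=2))
        assert res.p_corrected[2] == 0.0

    def test_smoothing_option_floors_p(self, rng):
        profiles, labels = simulate_bin_profiles(10, 10, rng, effect_bin=3, effect_size_d=50.0)
        res = permutation_fwe(
            profiles, labels, TFCEParams(n_permutations=200, seed=2, smoothing=True)
        )
        assert res.p_corrected[2] == pytest.approx(1.0 / 201.0)

    def test_one_sided_directions(self, rng):
        profiles, labels = simulate_bin_profiles(10, 10, rng, effect_bin=3, effect_size_d=50.0)
        pos = permutation_fwe(
            profiles, labels, TFCEParams(n_permutations=200, seed=2, sided="positive")
        )
        neg = permutation_fwe(
            profiles, labels, TFCEParams(n_permutations=200, seed=2, sided="negative")
        )
        assert pos.p_corrected[2] == 0.0
        assert not neg.significant.any()

    def test_deterministic_given_seed(self, rng):
        profiles, labels = simulate_bin_profiles(8, 8, rng)
        r1 = permutation_fwe(profiles, labels, TFCEParams(n_permutations=300, seed=5))
        r2 = permutation_fwe(profiles, labels, TFCEParams(n_permutations=300, seed=5))
        assert np.array_equal(r1.p_corrected, r2.p_corrected)
        assert np.array_equal(r1.null_maxima, r2.null_maxima)

    def test_missing_values_dropped_pairwise(self, rng):
        profiles, labels = simulate_bin_profiles(8, 8, rng)
        profiles[0, 3] = np.nan
        res = permutation_fwe(profiles, labels, TFCEParams(n_permutations=200, seed=0))
        assert np.all(np.isfinite(res.p_corrected))

    def test_quick_null_calibration(self):
        # loose unit-level check; the tight one is an acceptance criterion
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            profiles, labels = simulate_bin_profiles(10, 10, rng)
            res = permutation_fwe(profiles, labels, TFCEParams(n_permutations=300, seed=i))
            hits += bool(res.significant.any())
        assert 0.005 <= hits / n_rep <= 0.13


class TestWholeTract:
    def test_identical_groups_zero_d(self):
        p, d = whole_tract_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_large_sample_recovers_unit_d(self, rng):
        a = rng.normal(1.0, 1.0, size=10000)
        b = rng.normal(0.0, 1.0, size=10000)
        _, d = whole_tract_compare(a, b)
        assert abs(d - 1.0) < 0.05

    def test_antisymmetric(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20) + 1
        _, d1 = whole_tract_compare(a, b)
        _, d2 = whole_tract_compare(b, a)
        assert d1 == pytest.approx(-d2)

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ValueError):
            whole_tract_compare([1.0, 1.0], [1.0, 1.0])


class TestBarnard:
    def test_equal_proportions_p_one(self):
        assert barnard_exact([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_perfect_split_matches_oracle(self):
        ours = barnard_exact([[5, 0], [0, 5]])
        assert abs(ours - barnard_brute_p([[5, 0], [0, 5]])) < 1e-3

    def test_random_tables_match_oracle(self, rng):
        for _ in range(8):
            tbl = rng.integers(0, 7, size=(2, 2))
            if tbl[:, 0].sum() == 0 or tbl[:, 1].sum() == 0:
                continue
            assert abs(barnard_exact(tbl) - barnard_brute_p(tbl.tolist())) < 1e-3

    def test_matches_scipy(self, rng):
        # tables whose rejection sets hold no |T| ties; tied outcomes are
        # counted as rejecting here (and in the oracle) but not by scipy
        for tbl in ([[7, 2], [1, 6]], [[3, 5], [6, 1]], [[5, 2], [2, 6]]):
            ref = sps.barnard_exact(tbl, pooled=True).pvalue
            assert barnard_exact(tbl) == pytest.approx(float(ref), abs=2e-3)

    def test_symmetry_under_double_swap(self, rng):
        tbl = np.array([[6, 1], [2, 5]])
        swapped = tbl[::-1, ::-1]
        assert barnard_exact(tbl) == pytest.approx(barnard_exact(swapped), abs=1e-9)

    def test_empty_margin_is_one(self):
        assert barnard_exact([[0, 3], [0, 4]]) == 1.0

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            barnard_exact([[1.5, 2], [2, 2]])


class TestCrowding:
    def _rec(self, viq, piq):
        return SubjectRecord(subject_id="x", group="patient", viq=viq, piq=piq)

    def test_crowding_group_medians(self):
        label = classify_crowding(self._rec(85.5, 64.5))
        assert label.crowding
        assert label.delta == pytest.approx(21.0)

    def test_no_crowding_group_medians(self):
        label = classify_crowding(self._rec(71.5, 73.5))
        assert not label.crowding
        assert label.delta == pytest.approx(-2.0)

    def test_boundary_is_crowding(self):
        assert classify_crowding(self._rec(80.0, 70.0)).crowding

    def test_missing_score_unlabeled(self):
        assert classify_crowding(self._rec(np.nan, 70.0)) is None


class TestLogisticModels:
    def test_known_beta_recovered(self, rng):
        n = 2000
        x = rng.normal(size=(n, 3))
        beta = np.array([0.5, 1.5, -2.0])
        eta = 0.3 + x @ beta
        y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
        fit = fit_logistic(y.astype(float), x, terms=["a", "b", "c"])
        assert not fit.separation
        for est, se, true in zip(fit.coef[1:], fit.stderr[1:], beta):
            assert abs(est - true) < 4 * se

    def test_duplicated_covariate_reported(self, rng):
        n = 200
        x1 = rng.normal(size=n)
        y = (rng.random(n) < 0.5).astype(float)
        fit = fit_logistic(y, np.column_stack([x1, x1]), terms=["a", "a_copy"])
        assert fit.cond_number > 1e6

    def test_perfect_separation_flagged(self, rng):
        x = rng.normal(size=(60, 1))
        y = (x[:, 0] > 0).astype(float)
        with pytest.warns(UserWarning):
            fit = fit_logistic(y, x, terms=["a"])
        assert fit.separation
        assert np.all(np.isfinite(fit.stderr))

    def test_null_llr_p_roughly_uniform(self):
        pvals = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(400, 2))
            y = (rng.random(400) < 0.5).astype(float)
            pvals.append(fit_logistic(y, x, terms=["a", "b"]).llr_pvalue)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001

    def _subjects(self, rng, n=14):
        recs = []
        for i in range(n):
            crowding = i < n // 2
            viq = 80 + rng.normal(0, 5)
            piq = viq - (15 if crowding else -2) + rng.normal(0, 2)
            recs.append(
                SubjectRecord(
                    subject_id=f"p{i:02d}",
                    group="patient",
                    contralesional_hemisphere="right" if i % 2 else "left",
                    etiology="congenital" if crowding else "acquired",
                    viq=viq,
                    piq=piq,
                    age_at_scan=20 + rng.uniform(-5, 5),
                    age_at_surgery=10 + rng.uniform(-5, 5),
                    age_at_onset=3 + rng.uniform(0, 4),
                    skeleton_mean_fa=0.4,
                )
            )
        return recs

    def test_three_models_structure(self, rng):
        subjects = self._subjects(rng)
        fa = {r.subject_id: 1.0 + 0.1 * rng.normal() for r in subjects}
        models = fit_crowding_models(subjects, fa)
        assert [m.name for m in models] == ["model_1", "model_2", "model_3"]
        ages = [m.terms[1] for m in models]
        assert ages == ["age_at_surgery", "age_at_onset", "age_at_scan"]
        for m in models:
            assert m.terms[0] == "const"
            assert m.terms[2:] == ["norm_fa", "affected_hemisphere"]
            assert np.isfinite(m.bic)

    def test_too_few_subjects_rejected(self, rng):
        subjects = self._subjects(rng, n=6)
        fa = {r.subject_id: 1.0 for r in subjects}
        with pytest.raises(ValueError):
            fit_crowding_models(subjects, fa)
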