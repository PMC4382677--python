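"""Estimators of the neural-data toolkit: ROC, CTI, CS, CP, tuning fits,
GLM classification, noise correlations, dip test, classical MDS."""

import numpy as np
import pandas as pd
import pytest

from catcircuit.analysis import (TuningFit, category_sensitivity,
                                 choice_probability, classical_mds,
                                 cp_shuffle_test, cti, dip_statistic, dip_test,
                                 fit_category_tuning, fit_direction_tuning,
                                 glm_classify, infer_choice_from_match,
                                 noise_correlations, roc_area,
                                 tuning_curve_cti, width_constraint_band,
                                 _dir_profile)
from catcircuit.datasets import RateDataset
from catcircuit.task import assign_category
from catcircuit.theory import cp_gaussian

DIRS = [15.0, 45.0, 75.0, 105.0, 135.0, 165.0,
        195.0, 225.0, 255.0, 285.0, 315.0, 345.0]
CATS = np.array([assign_category(t, 0.0) for t in DIRS])


def make_dataset(rates, theta, choice=None, correct=None, valid=None,
                 pref=None):
    rates = np.asarray(rates, dtype=float)
    n = rates.shape[0]
    theta = np.asarray(theta, dtype=float)
    cat = np.array([assign_category(t, 0.0) for t in theta])
    if choice is None:
        choice = cat.copy()
    if correct is None:
        correct = np.asarray(choice) == cat
    if valid is None:
        valid = np.ones(n, dtype=bool)
    trials = pd.DataFrame({"theta_deg": theta, "category": cat,
                           "choice": choice, "correct": correct,
                           "valid": valid})
    neurons = pd.DataFrame({"pref_deg": pref if pref is not None
                            else np.full(rates.shape[1], np.nan)})
    return RateDataset(rates, trials, neurons)


class TestRocArea:
    def test_disjoint_samples(self):
        assert roc_area([3, 5], [1, 2]) == 1.0

    def test_identical_multisets(self):
        assert roc_area([1, 2, 3], [1, 2, 3]) == 0.5

    def test_enumerated_pairs(self):
        # pairs (1,2),(1,4),(3,2),(3,4): one win of four
        assert roc_area([1, 3], [2, 4]) == 0.25

    def test_complement_identity(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(30), rng.random(40)
        assert roc_area(x, y) == pytest.approx(1 - roc_area(y, x))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(25), rng.random(25)
        assert roc_area(np.exp(3 * x), np.exp(3 * y)) == \
            pytest.approx(roc_area(x, y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            roc_area([], [1.0])


class TestCTI:
    def test_step_tuning_is_fully_categorical(self):
        rates = np.where(CATS == "C1", 1.0, 0.0)
        assert tuning_curve_cti(rates, CATS) == 1.0

    def test_flat_tuning_is_zero_by_convention(self):
        assert tuning_curve_cti(np.full(12, 3.3), CATS) == 0.0

    def test_handbuilt_curve_matches_pair_enumeration(self):
        rates = np.array([2, 1, 0, 0, 1, 2, 0, 0, 0, 0, 0, 0], dtype=float)
        by_sep = {}
        for i in range(12):
            for j in range(i + 1, 12):
                sep = min(abs(DIRS[i] - DIRS[j]), 360 - abs(DIRS[i] - DIRS[j]))
                w, b = by_sep.setdefault(sep, ([], []))
                (w if CATS[i] == CATS[j] else b).append(abs(rates[i] - rates[j]))
        ws, bs = [], []
        for w, b in by_sep.values():
            if w and b:
                ws.append(np.mean(w)); bs.append(np.mean(b))
        expected = (np.mean(bs) - np.mean(ws)) / (np.mean(bs) + np.mean(ws))
        assert tuning_curve_cti(rates, CATS, DIRS) == pytest.approx(expected)

    def test_unimodal_curve_scores_near_zero(self):
        # separation matching removes the geometric bias of bell curves
        vals = [tuning_curve_cti(_dir_profile(np.array(DIRS), 1.0, 10.0, 90.0, p),
                                 CATS, DIRS)
                for p in np.arange(0.0, 360.0, 15.0)]
        assert abs(np.mean(vals)) < 0.05

    def test_affine_invariance_with_positive_scale(self):
        rng = np.random.default_rng(2)
        rates = rng.random(12)
        a = tuning_curve_cti(rates, CATS)
        b = tuning_curve_cti(3.7 * rates + 11.0, CATS)
        assert a == pytest.approx(b)


class TestCategorySensitivity:
    def test_separated_categories_give_extreme_cs(self):
        theta = np.tile(DIRS, 4)
        rates = np.where(np.isin(theta, DIRS[:6]), 10.0, 1.0)[:, None]
        ds = make_dataset(rates, theta)
        assert category_sensitivity(ds, 0) == 1.0

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(3)
        theta = np.tile(DIRS, 20)
        rates = rng.random((len(theta), 1))
        ds = make_dataset(rates, theta)
        assert category_sensitivity(ds, 0) == pytest.approx(0.5, abs=0.08)

    def test_missing_category_yields_nan(self):
        theta = np.full(10, 15.0)
        ds = make_dataset(np.ones((10, 1)), theta)
        assert np.isnan(category_sensitivity(ds, 0))


class TestChoiceProbability:
    def test_low_count_stimuli_excluded(self):
        # stimulus 15: only 2 C1-choice trials -> excluded; stimulus 195:
        # 3 of each -> the neuron CP equals that stimulus's ROC area
        theta = np.array([15.0] * 5 + [195.0] * 6)
        choice = np.array(["C1", "C1", "C2", "C2", "C2",
                           "C1", "C1", "C1", "C2", "C2", "C2"])
        rates = np.arange(11, dtype=float)[:, None]
        ds = make_dataset(rates, theta, choice=choice)
        cp, per = choice_probability(ds, 0, return_details=True)
        assert set(per) == {195.0}
        assert np.isnan(cp)  # no valid estimate in category C1 -> excluded

    def test_inclusion_requires_both_categories(self):
        theta = np.array([15.0] * 6 + [195.0] * 6)
        choice = np.array(["C1", "C1", "C1", "C2", "C2", "C2"] * 2)
        rates = np.arange(12, dtype=float)[:, None]
        ds = make_dataset(rates, theta, choice=choice)
        cp = choice_probability(ds, 0)
        assert not np.isnan(cp)

    def test_choice_independent_rates_near_half(self):
        rng = np.random.default_rng(4)
        theta = np.tile([15.0, 195.0], 60)
        choice = rng.choice(["C1", "C2"], 120)
        rates = rng.random((120, 1))
        ds = make_dataset(rates, theta, choice=choice)
        assert choice_probability(ds, 0) == pytest.approx(0.5, abs=0.1)

    def test_consistency_with_gaussian_generative_rule(self):
        rng = np.random.default_rng(5)
        n = 4000
        theta = np.tile([15.0, 195.0], n // 2)
        choice = rng.choice(["C1", "C2"], n)
        shift = np.where(choice == "C1", 55.0, 50.0)
        rates = (shift + 5.0 * rng.standard_normal(n))[:, None]
        ds = make_dataset(rates, theta, choice=choice)
        assert choice_probability(ds, 0) == \
            pytest.approx(cp_gaussian(55, 50, 5), abs=0.02)


class TestCpShuffleTest:
    def test_null_rates_rarely_significant(self):
        rng = np.random.default_rng(6)
        rejections = 0
        for rep in range(10):
            theta = np.tile([15.0, 195.0], 30)
            choice = rng.choice(["C1", "C2"], 60)
            rates = rng.random((60, 1))
            ds = make_dataset(rates, theta, choice=choice)
            _, p = cp_shuffle_test(ds, 0, n_shuffles=200, rng=rng)
            rejections += p < 0.05
        assert rejections <= 2

    def test_choice_locked_rates_detected(self):
        rng = np.random.default_rng(7)
        theta = np.tile([15.0, 195.0], 40)
        choice = rng.choice(["C1", "C2"], 80)
        rates = (np.where(choice == "C1", 10.0, 2.0)
                 + 0.5 * rng.standard_normal(80))[:, None]
        ds = make_dataset(rates, theta, choice=choice)
        cp, p = cp_shuffle_test(ds, 0, n_shuffles=200, rng=rng)
        assert cp > 0.95 and p < 0.001


class TestInferChoice:
    def test_match_implies_test_category(self):
        assert infer_choice_from_match("C1", "match", 45.0) == "C1"

    def test_nonmatch_implies_other_category(self):
        assert infer_choice_from_match("C1", "nonmatch", 75.0) == "C2"

    def test_near_boundary_test_excluded(self):
        assert infer_choice_from_match("C1", "match", 15.0) is None


class TestNoiseCorrelations:
    def test_duplicated_neuron_perfectly_correlated(self):
        rng = np.random.default_rng(8)
        theta = np.tile([15.0, 195.0], 20)
        base = rng.random(40)
        rates = np.column_stack([base, base, rng.random(40)])
        ds = make_dataset(rates, theta)
        r = noise_correlations(ds)
        assert r[0, 1] == pytest.approx(1.0)

    def test_independent_neurons_scale_as_null(self):
        rng = np.random.default_rng(9)
        theta = np.tile([15.0, 195.0], 100)
        rates = rng.standard_normal((200, 6)) + 5
        ds = make_dataset(rates, theta)
        r = noise_correlations(ds)
        off = r[np.triu_indices(6, 1)]
        assert np.mean(np.abs(off)) < 3 / np.sqrt(200)

    def test_handcomputed_two_neuron_example(self):
        theta = np.array([15.0, 15.0, 195.0, 195.0])
        rates = np.array([[1.0, 2.0], [3.0, 1.0], [0.0, 0.0], [2.0, 4.0]])
        ds = make_dataset(rates, theta)
        # per stimulus: two points -> correlation is +-1
        r12_a = np.corrcoef(rates[:2, 0], rates[:2, 1])[0, 1]   # -1
        r12_b = np.corrcoef(rates[2:, 0], rates[2:, 1])[0, 1]   # +1
        expected = (r12_a + r12_b) / 2
        assert noise_correlations(ds)[0, 1] == pytest.approx(expected)


class TestTuningFits:
    def test_parameters_recovered_from_noiseless_curve(self):
        true = dict(r0=2.0, rmax=12.0, w_deg=95.0, theta0_deg=135.0)
        rates = _dir_profile(np.array(DIRS), **true)
        fit = fit_direction_tuning(DIRS, rates)
        assert fit.converged
        assert fit.theta0_deg == pytest.approx(135.0, abs=1.0)
        assert fit.w_deg == pytest.approx(95.0, rel=0.05)
        assert fit.rmax == pytest.approx(12.0, rel=0.05)

    def test_flat_curve_flagged(self):
        fit = fit_direction_tuning(DIRS, np.full(12, 4.0))
        assert not fit.converged

    def test_category_step_profile(self):
        rates = np.where(CATS == "C1", 7.0, 3.0)
        assert fit_category_tuning(DIRS, rates) == (7.0, 3.0)
        c1m, c2m = fit_category_tuning(DIRS, np.arange(12, dtype=float))
        assert c1m == pytest.approx(np.arange(6).mean())
        assert c2m == pytest.approx(np.arange(6, 12).mean())

    def test_width_band_is_decile_around_median(self):
        # a population whose 45th/55th percentiles sit at the published
        # association-neuron band endpoints
        widths = np.linspace(101.4, 142.7, 11)  # median 122.05
        lo, hi = width_constraint_band(widths, 10.0)
        assert lo == pytest.approx(np.percentile(widths, 45))
        assert hi == pytest.approx(np.percentile(widths, 55))


class TestGlmClassify:
    def _dataset(self, kind, rng, snr=6.0):
        theta = np.tile(DIRS, 25)
        cat = np.array([assign_category(t, 0.0) for t in theta])
        base = np.zeros(len(theta))
        if kind in ("direction", "mixed"):
            base += snr * _dir_profile(theta, 0.0, 1.0, 100.0, 75.0)
        if kind in ("category", "mixed"):
            base += snr * np.where(cat == "C1", 0.5, -0.5)
        rates = (base + rng.standard_normal(len(theta)))[:, None]
        return make_dataset(rates, theta)

    @pytest.mark.parametrize("kind", ["direction", "category", "mixed"])
    def test_high_snr_labels_recovered(self, kind):
        rng = np.random.default_rng(10)
        ds = self._dataset(kind, rng)
        fit = glm_classify(ds, 0, n_shuffles=300, rng=rng)
        assert fit.label == kind

    def test_pure_noise_mostly_nonselective(self):
        rng = np.random.default_rng(11)
        labels = []
        for _ in range(10):
            ds = self._dataset("direction", rng, snr=0.0)
            labels.append(glm_classify(ds, 0, n_shuffles=200, rng=rng).label)
        assert labels.count("nonselective") >= 7

    def test_loo_lambda_matches_bruteforce(self):
        from catcircuit.analysis import _ridge_loo_lambda
        rng = np.random.default_rng(12)
        X = rng.standard_normal((40, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.standard_normal(40)
        lambdas = np.logspace(-3, 2, 7)
        best = _ridge_loo_lambda(X, y, lambdas)
        # brute force leave-one-out
        mses = []
        for lam in lambdas:
            errs = []
            for i in range(40):
                m = np.ones(40, bool); m[i] = False
                beta = np.linalg.solve(X[m].T @ X[m] + lam * np.eye(3),
                                       X[m].T @ y[m])
                errs.append((y[i] - X[i] @ beta) ** 2)
            mses.append(np.mean(errs))
        assert best == lambdas[int(np.argmin(mses))]


class TestDipTest:
    def test_two_point_sample_attains_maximal_dip(self):
        rng = np.random.default_rng(13)
        x = np.r_[rng.uniform(0, 1e-3, 300), rng.uniform(1, 1 + 1e-3, 300)]
        assert dip_statistic(x) == pytest.approx(0.25, abs=0.01)

    def test_unimodal_sample_usually_not_significant(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(150)
        _, p = dip_test(x, n_boot=300, rng=rng)
        assert p > 0.05

    def test_separated_clusters_detected(self):
        rng = np.random.default_rng(15)
        x = np.r_[rng.standard_normal(75) - 4, rng.standard_normal(75) + 4]
        _, p = dip_test(x, n_boot=300, rng=rng)
        assert p < 0.01

    def test_affine_invariance(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(200)
        assert dip_statistic(x) == pytest.approx(dip_statistic(5 * x - 3),
                                                 rel=1e-9)

    def test_circular_unwrapping_around_boundary(self):
        rng = np.random.default_rng(17)
        # two clusters at the category centres +-90 deg
        x = np.r_[90 + 10 * rng.standard_normal(60),
                  270 + 10 * rng.standard_normal(60)] % 360
        _, p = dip_test(x, n_boot=300, rng=rng, boundary_deg=0.0)
        assert p < 0.01


class TestClassicalMDS:
    def test_planar_circle_recovered_exactly(self):
        ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        ring = np.column_stack([np.cos(ang), np.sin(ang)])
        rng = np.random.default_rng(18)
        # embed the planar ring in 40-d by a random rotation
        Q, _ = np.linalg.qr(rng.standard_normal((40, 2)))
        M = ring @ Q.T
        coords, evals = classical_mds(M)
        assert evals[1] > 1e-10 and abs(evals[2]) < 1e-8
        # Procrustes: distances to centre all equal, adjacent spacing equal
        radii = np.linalg.norm(coords, axis=1)
        np.testing.assert_allclose(radii, 1.0, atol=1e-8)
        d = np.linalg.norm(np.diff(np.vstack([coords, coords[:1]]), axis=0),
                           axis=1)
        np.testing.assert_allclose(d, d[0], atol=1e-8)

    def test_eigenvalue_spectrum_sorted(self):
        rng = np.random.default_rng(19)
        M = rng.standard_normal((10, 30))
        _, evals = classical_mds(M)
        assert np.all(np.diff(evals) <= 1e-9)

    def test_too_few_stimuli_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(np.zeros((2, 5)))
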