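import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from morphsense import (
    BinnedData,
    PsychometricCurve,
    PsychometricParams,
    UnattainableCriterionError,
    UnfittableError,
    bootstrap_threshold_ci,
    eval_logistic,
    eval_performance,
    fit_pf,
    neg_log_likelihood,
    threshold_dilution,
    threshold_from_params,
)
from morphsense.psychometric import InvalidParameterError

from conftest import binomial_counts, expected_counts


class TestLogistic:
    @pytest.mark.parametrize(
        "x, alpha, beta, expected",
        [
            (5.0, 5.0, 0.7, 0.5),  # midpoint
            (math.log(3.0) / 0.4, 0.0, 0.4, 0.75),  # ln(3)/beta above midpoint
            (2.0, 0.0, 1.0, 0.8807970779778823),
        ],
    )
    def test_values(self, x, alpha, beta, expected):
        assert eval_logistic(x, alpha, beta) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_slope(self):
        with pytest.raises(InvalidParameterError):
            eval_logistic(0.0, 0.0, 0.0)
        with pytest.raises(InvalidParameterError):
            eval_logistic(0.0, 0.0, -1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        alpha=st.floats(-40, 140),
        beta=st.floats(0.01, 5),
        d=st.floats(0, 60),
    )
    def test_midpoint_symmetry(self, alpha, beta, d):
        """F(alpha + d) + F(alpha - d) = 1 for every valid slope."""
        total = eval_logistic(alpha + d, alpha, beta) + eval_logistic(
            alpha - d, alpha, beta
        )
        assert total == pytest.approx(1.0, abs=1e-9)


class TestPerformance:
    def test_criterion_at_threshold(self):
        p = PsychometricParams(alpha=10.0, beta=0.3, gamma=0.5, lapse=0.0)
        assert eval_performance(10.0, p) == pytest.approx(0.75, abs=1e-12)

    def test_asymptotes(self):
        p = PsychometricParams(alpha=10.0, beta=0.5, gamma=0.5, lapse=0.02)
        assert eval_performance(-1e4, p) == pytest.approx(0.5, abs=1e-9)
        assert eval_performance(1e4, p) == pytest.approx(0.98, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(
        alpha=st.floats(-20, 120),
        beta=st.floats(0.01, 5),
        lapse=st.floats(0, 0.2),
    )
    def test_monotone_in_intensity(self, alpha, beta, lapse):
        p = PsychometricParams(alpha=alpha, beta=beta, gamma=0.5, lapse=lapse)
        x = np.linspace(-50, 150, 101)
        psi = eval_performance(x, p)
        assert np.all(np.diff(psi) >= -1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha=0, beta=-1),
            dict(alpha=0, beta=1, gamma=1.0),
            dict(alpha=0, beta=1, lapse=1.0),
            dict(alpha=0, beta=1, gamma=0.6, lapse=0.5),
            dict(alpha=math.inf, beta=1),
        ],
    )
    def test_parameter_validation(self, kwargs):
        with pytest.raises(InvalidParameterError):
            PsychometricParams(**kwargs)


class TestBinnedData:
    def test_sorts_levels(self):
        d = BinnedData([90.0, 70.0, 80.0], [10, 10, 10], [5, 9, 7])
        assert list(d.dilution_pct) == [70.0, 80.0, 90.0]
        assert list(d.n_correct) == [9, 7, 5]
        np.testing.assert_allclose(d.intensity_pct + d.dilution_pct, 100.0)

    @pytest.mark.parametrize(
        "levels, n, k",
        [
            ([70, 70], [10, 10], [5, 5]),  # duplicate level
            ([70], [10], [11]),  # k > n
            ([105], [10], [5]),  # out of range
            ([70], [0], [0]),  # no trials anywhere
        ],
    )
    def test_invalid(self, levels, n, k):
        with pytest.raises(ValueError):
            BinnedData(levels, n, k)


class TestNegLogLikelihood:
    def test_hand_values(self):
        p50 = PsychometricParams(alpha=30.0, beta=1.0, gamma=0.0)  # psi(30)=0.5
        d = BinnedData([70.0], [10.0], [5.0])
        assert neg_log_likelihood(d, p50) == pytest.approx(10 * math.log(2), rel=1e-9)

        # psi = 0.75 exactly at the threshold with the 2IFC wrapper
        p75 = PsychometricParams(alpha=30.0, beta=1.0, gamma=0.5)
        d2 = BinnedData([70.0], [10.0], [10.0])
        assert neg_log_likelihood(d2, p75) == pytest.approx(
            -10 * math.log(0.75), rel=1e-9
        )

    def test_additive_over_disjoint_levels(self, true_params):
        a = BinnedData([70.0, 80.0], [20, 20], [19, 16])
        b = BinnedData([85.0, 90.0], [20, 20], [14, 11])
        union = BinnedData(
            [70.0, 80.0, 85.0, 90.0], [20, 20, 20, 20], [19, 16, 14, 11]
        )
        assert neg_log_likelihood(union, true_params) == pytest.approx(
            neg_log_likelihood(a, true_params) + neg_log_likelihood(b, true_params),
            rel=1e-12,
        )

    def test_finite_under_zero_lapse(self):
        # all-correct data at very low intensity would hit log(0) unclamped
        p = PsychometricParams(alpha=90.0, beta=5.0, gamma=0.5, lapse=0.0)
        d = BinnedData([99.0], [10.0], [10.0])
        assert np.isfinite(neg_log_likelihood(d, p))


class TestFit:
    def test_recovers_noiseless_truth(self, true_params, noiseless_data):
        fit = fit_pf(noiseless_data)
        assert fit.fittable and fit.converged
        assert fit.params.alpha == pytest.approx(true_params.alpha, rel=1e-3)
        assert fit.params.beta == pytest.approx(true_params.beta, rel=1e-3)
        assert fit.log_likelihood == pytest.approx(
            -neg_log_likelihood(noiseless_data, fit.params), rel=1e-12
        )

    def test_flat_chance_data_unfittable(self):
        d = BinnedData(
            [70.0, 80.0, 90.0, 95.0], [40.0] * 4, [20.0] * 4
        )
        fit = fit_pf(d)
        assert not fit.fittable
        assert fit.reason is not None
        with pytest.raises(UnfittableError):
            threshold_dilution(fit)

    def test_order_invariance(self, true_params, seven_levels):
        rng = np.random.default_rng(7)
        data = binomial_counts(true_params, seven_levels, 120, rng)
        perm = np.array([3, 0, 6, 1, 5, 2, 4])
        shuffled = BinnedData(
            data.dilution_pct[perm], data.n_trials[perm], data.n_correct[perm]
        )
        f1, f2 = fit_pf(data), fit_pf(shuffled)
        assert f1.params.alpha == pytest.approx(f2.params.alpha, abs=1e-9)
        assert f1.params.beta == pytest.approx(f2.params.beta, abs=1e-12)

    def test_grid_never_beats_optimizer(self, sampled_data):
        """Coarse-grid oracle: no (alpha, beta) grid point attains a lower NLL."""
        fit = fit_pf(sampled_data)
        a0, b0 = fit.params.alpha, fit.params.beta
        width = math.log(3.0) / b0  # distance from midpoint to the 75% point
        best_nll = -fit.log_likelihood
        alphas = np.linspace(a0 - 3 * width, a0 + 3 * width, 201)
        betas = np.geomspace(b0 / 4, 4 * b0, 201)
        for a in alphas:
            for b in betas[::10]:
                p = PsychometricParams(a, b, fit.params.gamma, fit.params.lapse)
                assert neg_log_likelihood(sampled_data, p) >= best_nll - 1e-6

    def test_bootstrap_interval_covers_truth(self, true_params, seven_levels):
        """Nominal 95% bootstrap CIs cover the generating threshold >= 90% of the time."""
        rng = np.random.default_rng(99)
        true_thr = true_params.threshold_dilution
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            data = binomial_counts(true_params, seven_levels, 240, rng)
            fit = fit_pf(data)
            lo, hi = bootstrap_threshold_ci(
                data, fit, n_boot=199, seed=int(rng.integers(2**31))
            )
            hits += lo <= true_thr <= hi
        assert hits / n_rep >= 0.90


class TestThreshold:
    def test_dilution_scale(self):
        p = PsychometricParams(alpha=14.0, beta=0.3)
        assert threshold_from_params(p) == pytest.approx(86.0, abs=1e-12)

    def test_unattainable_criterion(self):
        p = PsychometricParams(alpha=10.0, beta=0.3, gamma=0.5, lapse=0.02)
        with pytest.raises(UnattainableCriterionError):
            threshold_from_params(p, criterion=0.99)

    @settings(deadline=None, max_examples=50)
    @given(
        alpha=st.floats(-20, 120),
        beta=st.floats(0.02, 5),
        lapse=st.floats(0, 0.1),
        criterion=st.floats(0.55, 0.85),
    )
    def test_round_trip_to_criterion(self, alpha, beta, lapse, criterion):
        p = PsychometricParams(alpha=alpha, beta=beta, gamma=0.5, lapse=lapse)
        thr = threshold_from_params(p, criterion)
        assert eval_performance(100.0 - thr, p) == pytest.approx(
            criterion, abs=1e-9
        )


class TestEstimator:
    def test_matches_functional_fit(self, true_params, seven_levels):
        rng = np.random.default_rng(5)
        data = binomial_counts(true_params, seven_levels, 120, rng)
        functional = fit_pf(data)
        est = PsychometricCurve().fit(
            data.dilution_pct.reshape(-1, 1),
            data.proportion_correct,
            sample_weight=data.n_trials,
        )
        assert est.alpha_ == pytest.approx(functional.params.alpha, abs=1e-8)
        assert est.threshold_ == pytest.approx(
            threshold_dilution(functional), abs=1e-8
        )
        psi = est.predict([[88.0]])
        assert 0.5 < psi[0] < 1.0

    def test_per_trial_input(self):
        rng = np.random.default_rng(11)
        p = PsychometricParams(alpha=10.0, beta=0.4)
        dil = np.repeat([78.0, 84.0, 88.0, 92.0, 96.0], 200)
        psi = eval_performance(100.0 - dil, p)
        y = (rng.random(dil.size) < psi).astype(float)
        est = PsychometricCurve().fit(dil, y)
        assert est.fittable_
        assert est.threshold_ == pytest.approx(90.0, abs=3.0)

    def test_sklearn_protocol(self):
        est = PsychometricCurve(lapse=0.01, n_starts=5)
        params = est.get_params()
        assert params["lapse"] == 0.01 and params["n_starts"] == 5
        cloned = clone(est)
        assert cloned.get_params() == params
        with pytest.raises(RuntimeError):
            est.predict([[80.0]])
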