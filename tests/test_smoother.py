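"""Bayesian single-trial estimator: operators, smoothing, tuning, AR/FPE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayeserp.simulate import DEFAULT_NOISE, NoiseSpec, RawEpoch, make_epoch, sample_ar_noise
from bayeserp.smoother import (
    ARModel,
    BayesianERPSmoother,
    SmootherConfig,
    calibrate_gamma_star,
    difference_matrix,
    estimate_single_trial,
    fit_ar_fpe,
    smooth,
    tune_gamma_discrepancy,
    whitening_matrix,
    wrss,
)


def _ar(coeffs, sigma2=1.0):
    c = np.atleast_1d(np.asarray(coeffs, float))
    return ARModel(p=c.size, coeffs=c, sigma2=sigma2, fpe=0.0)


def _lstsq_oracle(y, A, F, gamma):
    """Independent minimizer of ||A(y-u)||^2 + gamma*||Fu||^2 via stacked lstsq."""
    M = np.vstack([A, np.sqrt(gamma) * F])
    b = np.concatenate([A @ y, np.zeros(F.shape[0])])
    u, *_ = np.linalg.lstsq(M, b, rcond=None)
    return u


class TestWhitening:
    def test_order_zero_is_identity(self):
        A = whitening_matrix(ARModel(p=0, coeffs=np.empty(0), sigma2=1.0, fpe=0.0), 4)
        assert np.array_equal(A, np.eye(4))

    def test_ar1_rows(self):
        A = whitening_matrix(_ar([0.8]), 3)
        assert np.allclose(A, [[1, 0, 0], [-0.8, 1, 0], [0, -0.8, 1]])

    def test_whitening_property_on_long_ar1(self):
        ns = NoiseSpec(ar_coeffs=(0.8,), innovation_var=2.0)
        v = sample_ar_noise(ns, 52_000, seed=4)
        n = 2000
        A = whitening_matrix(_ar([0.8], sigma2=2.0), n)
        # whiten consecutive blocks with the banded operator
        w = np.concatenate([(A @ v[i : i + n])[1:] for i in range(0, 50_000, n)])
        assert w.var() == pytest.approx(2.0, rel=0.05)


class TestDifference:
    def test_first_difference_rows(self):
        F = difference_matrix(1, 3)
        assert np.allclose(F, [[1, 0, 0], [-1, 1, 0], [0, -1, 1]])

    def test_second_difference_annihilates_affine_tail(self):
        k = np.arange(20.0)
        F = difference_matrix(2, 20)
        out = F @ (3.0 * k + 7.0)
        assert np.allclose(out[2:], 0.0, atol=1e-12)

    def test_invertible(self):
        F = difference_matrix(2, 50)
        assert np.allclose(np.linalg.inv(F) @ F, np.eye(50), atol=1e-9)

    def test_inverse_is_double_cumsum(self, rng):
        w = rng.normal(size=30)
        F = difference_matrix(2, 30)
        assert np.allclose(np.linalg.solve(F, w), np.cumsum(np.cumsum(w)), atol=1e-9)


class TestSmooth:
    def test_gamma_zero_is_identity(self, rng):
        y = rng.normal(size=40)
        A = whitening_matrix(_ar([0.7]), 40)
        F = difference_matrix(2, 40)
        assert np.array_equal(smooth(y, A, F, 0.0), y)

    def test_matches_lstsq_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 51))
            y = rng.normal(size=n)
            a1 = rng.uniform(-0.9, 0.9)
            A = whitening_matrix(_ar([a1]), n)
            F = difference_matrix(2, n)
            gamma = 10.0 ** rng.uniform(-2, 4)
            u = smooth(y, A, F, gamma)
            assert np.allclose(u, _lstsq_oracle(y, A, F, gamma), atol=1e-8)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        a=st.floats(-3, 3, allow_nan=False),
        b=st.floats(-3, 3, allow_nan=False),
        seed=st.integers(0, 1000),
    )
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        n = 25
        y1, y2 = rng.normal(size=n), rng.normal(size=n)
        A = whitening_matrix(_ar([0.6]), n)
        F = difference_matrix(2, n)
        lhs = smooth(a * y1 + b * y2, A, F, 2.0)
        rhs = a * smooth(y1, A, F, 2.0) + b * smooth(y2, A, F, 2.0)
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_nonfinite_input_rejected(self):
        A = np.eye(5)
        F = difference_matrix(2, 5)
        with pytest.raises(ValueError):
            smooth(np.array([1.0, np.nan, 0, 0, 0]), A, F, 1.0)


class TestWRSS:
    def test_zero_residual(self, rng):
        y = rng.normal(size=10)
        assert wrss(y, y, np.eye(10)) == 0.0

    def test_identity_whitening_is_rss(self, rng):
        y, u = rng.normal(size=10), rng.normal(size=10)
        assert wrss(y, u, np.eye(10)) == pytest.approx(np.sum((y - u) ** 2))

    def test_matches_elementwise_norm(self, rng):
        y, u = rng.normal(size=10), rng.normal(size=10)
        A = whitening_matrix(_ar([0.5, -0.2]), 10)
        assert wrss(y, u, A) == pytest.approx(float(np.linalg.norm(A @ (y - u)) ** 2))


class TestDiscrepancyTuning:
    def test_converged_solution_satisfies_discrepancy(self, template):
        ep = make_epoch(template, DEFAULT_NOISE, "target", 0.0, seed=2)
        est = estimate_single_trial(ep)
        assert est.converged
        assert est.wrss == pytest.approx(200 * est.ar.sigma2, rel=2e-3)

    def test_wrss_monotone_in_gamma(self, rng):
        y = rng.normal(size=100) + np.linspace(0, 2, 100)
        A = whitening_matrix(_ar([0.5]), 100)
        F = difference_matrix(2, 100)
        gammas = np.logspace(-4, 8, 20)
        values = [wrss(y, smooth(y, A, F, g), A) for g in gammas]
        assert np.all(np.diff(values) >= -1e-9 * np.abs(values[:-1]))

    def test_noise_epochs_get_heavier_smoothing_than_targets(self, template):
        g_noise, g_target = [], []
        for i in range(40):
            epn = make_epoch(template, DEFAULT_NOISE, "nontarget", 6.0, seed=500 + i)
            ept = make_epoch(template, DEFAULT_NOISE, "target", 6.0, seed=500 + i)
            g_noise.append(np.log10(estimate_single_trial(epn).gamma))
            g_target.append(np.log10(estimate_single_trial(ept).gamma))
        assert np.mean(g_noise) > np.mean(g_target)

    def test_unbracketed_root_clamps_without_convergence(self):
        # huge claimed noise variance: even gamma_hi leaves WRSS below target
        y = np.zeros(50)
        A = np.eye(50)
        F = difference_matrix(2, 50)
        gamma, erp = tune_gamma_discrepancy(y, A, F, sigma2=1e6, config=SmootherConfig())
        assert gamma == SmootherConfig().gamma_bounds[1]
        assert not erp.converged


class TestARFPE:
    def test_white_noise_variance_recovered(self, rng):
        x = rng.normal(0.0, 2.0, size=100)
        model = fit_ar_fpe(x - x.mean())
        assert model.sigma2 == pytest.approx(x.var(), rel=0.1)

    def test_fpe_computed_for_every_candidate_order(self, rng):
        x = rng.normal(size=100)
        model = fit_ar_fpe(x - x.mean(), p_max=8)
        assert sorted(model.fpe_path) == list(range(1, 9))
        assert model.fpe == min(model.fpe_path.values())

    def test_ar2_order_and_coefficients_recovered(self):
        ns = NoiseSpec(ar_coeffs=(1.2, -0.5), innovation_var=1.0)
        rng = np.random.default_rng(3)
        orders, coeffs = [], []
        for _ in range(50):
            x = sample_ar_noise(ns, 100, seed=rng)
            m = fit_ar_fpe(x - x.mean())
            orders.append(m.p)
            if m.p >= 2:
                coeffs.append(m.coeffs[:2])
        values, counts = np.unique(orders, return_counts=True)
        assert values[np.argmax(counts)] == 2
        assert np.all(np.abs(np.mean(coeffs, axis=0) - [1.2, -0.5]) < 0.15)

    def test_p_max_validation(self, rng):
        with pytest.raises(ValueError):
            fit_ar_fpe(rng.normal(size=20), p_max=10)


class TestGammaStar:
    def test_median_of_single_value(self):
        assert calibrate_gamma_star([7.5]).value == 7.5

    def test_median_conventions(self):
        assert calibrate_gamma_star([1.0, 10.0, 100.0]).value == 10.0
        assert calibrate_gamma_star([1.0, 3.0]).value == 2.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibrate_gamma_star([])


class TestSingleTrial:
    def test_noise_free_target_recovered(self, template, rng):
        ep = RawEpoch(pre=rng.normal(0, 1, 100), post=template.waveform.copy(), label="target")
        est = estimate_single_trial(ep, gamma_star=1.0)
        rel_rmse = np.sqrt(np.mean((est.u_hat - template.waveform) ** 2)) / np.sqrt(
            np.mean(template.waveform**2)
        )
        assert rel_rmse < 0.05

    def test_nontarget_estimates_shrink_toward_flat(self, template):
        norms_u, norms_y = [], []
        for i in range(20):
            ep = make_epoch(template, DEFAULT_NOISE, "nontarget", 0.0, seed=900 + i)
            est = estimate_single_trial(ep)
            norms_u.append(np.linalg.norm(est.u_hat))
            norms_y.append(np.linalg.norm(ep.post - ep.pre.mean()))
        assert np.mean(norms_u) < 0.8 * np.mean(norms_y)

    def test_population_mean_nearly_unbiased(self, template):
        ests, raws = [], []
        for i in range(50):
            ep = make_epoch(template, DEFAULT_NOISE, "target", 6.0, seed=2000 + i)
            ests.append(estimate_single_trial(ep).u_hat)
            raws.append(ep.post - ep.pre.mean())
        deviation = np.abs(np.mean(ests, axis=0) - np.mean(raws, axis=0))
        noise_sd = float(np.std(np.asarray(raws) - np.mean(raws, axis=0)))
        assert deviation.max() < 6.0 * noise_sd / np.sqrt(50)


class TestSmootherEstimator:
    def test_gamma_star_is_median_of_epoch_gammas(self, template):
        eps = [make_epoch(template, DEFAULT_NOISE, "target", 6.0, seed=i) for i in range(9)]
        X = np.stack([np.concatenate([e.pre, e.post]) for e in eps])
        sm = BayesianERPSmoother().fit(X)
        assert sm.gamma_star_ == pytest.approx(np.median(sm.gammas_))

    def test_transform_uses_fixed_gamma(self, template):
        eps = [make_epoch(template, DEFAULT_NOISE, "target", 6.0, seed=i) for i in range(5)]
        X = np.stack([np.concatenate([e.pre, e.post]) for e in eps])
        sm = BayesianERPSmoother().fit(X)
        out = sm.transform(X)
        expected = np.stack(
            [
                estimate_single_trial(e, gamma_star=sm.gamma_star_).u_hat
                for e in eps
            ]
        )
        assert np.allclose(out, expected, atol=1e-10)

    def test_sklearn_param_interface(self):
        sm = BayesianERPSmoother(p_max=5)
        assert sm.get_params()["p_max"] == 5
        sm.set_params(m=1)
        assert sm.m == 1
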