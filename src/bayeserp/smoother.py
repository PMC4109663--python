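"""Bayesian single-trial ERP estimation.

The poststimulus sweep is modeled as y = u + v, where the unknown ERP u is
a priori the result of m discrete integrations of white noise with variance
λ² (m = 2 by default: a smooth, twice-integrated prior) and the background
EEG v follows an AR(p) model with innovation variance σ², identified from
the prestimulus samples of the same epoch via the FPE order-selection
criterion.  With A the AR whitening operator and F the m-th difference
operator, the MAP estimate is the Tikhonov-type smoother

    û = (AᵀA + γ FᵀF)⁻¹ AᵀA y,      γ = σ² / λ²,

the minimizer of (y−u)ᵀAᵀA(y−u) + γ‖Fu‖².  γ is tuned per epoch by the
discrepancy criterion — choose γ so the whitened residual energy
WRSS(γ) = (y−û)ᵀAᵀA(y−û) equals its expected value n·σ² — during
calibration; for testing a fixed γ*, the median of the calibration γ
values, is used so the smoother is a fixed linear filter.

All linear algebra goes through symmetric banded Cholesky solves
(scipy.linalg.solveh_banded); AᵀA + γFᵀF has bandwidth max(p, m) ≪ n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .epoching import baseline_correct, baseline_correct_array
from .simulate import N_POST, N_PRE, RawEpoch

__all__ = [
    "ARModel",
    "SmootherConfig",
    "EstimatedERP",
    "GammaStar",
    "fit_ar_fpe",
    "whitening_matrix",
    "difference_matrix",
    "smooth",
    "wrss",
    "tune_gamma_discrepancy",
    "calibrate_gamma_star",
    "estimate_single_trial",
    "BayesianERPSmoother",
]


@dataclass(frozen=True)
class ARModel:
    """AR(p) background-noise model fitted to prestimulus data."""

    p: int
    coeffs: np.ndarray
    sigma2: float
    fpe: float
    fpe_path: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", np.atleast_1d(np.asarray(self.coeffs, float)))
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass(frozen=True)
class SmootherConfig:
    """Tunables of the single-trial estimator."""

    m: int = 2
    p_max: int = 10
    gamma_bounds: tuple = (1e-4, 1e8)
    discrepancy_rel_tol: float = 1e-3
    max_iter: int = 60

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        lo, hi = self.gamma_bounds
        if not 0 < lo < hi:
            raise ValueError("gamma_bounds must satisfy 0 < lo < hi")


@dataclass(frozen=True)
class EstimatedERP:
    """Smoothed poststimulus waveform with estimation diagnostics."""

    u_hat: np.ndarray
    gamma: float
    ar: ARModel
    wrss: float
    converged: bool
    mode: str = "per_epoch_discrepancy"
    label: str = ""


@dataclass(frozen=True)
class GammaStar:
    """Fixed regularization for testing: median of calibration γ values."""

    value: float
    n_calibration_epochs: int
    source_gammas: np.ndarray


def _stabilize(a: np.ndarray) -> np.ndarray:
    """Reflect AR roots outside the unit circle back inside (keeps |A| well
    conditioned; the spectral shape is preserved up to an all-pass factor)."""
    if a.size == 0:
        return a
    roots = np.roots(np.r_[1.0, -a])
    bad = np.abs(roots) >= 1.0
    if not np.any(bad):
        return a
    roots[bad] = (1.0 - 1e-8) / np.conj(roots[bad])
    poly = np.poly(roots).real
    return -poly[1:]


def fit_ar_fpe(prestim: np.ndarray, p_max: int = 10) -> ARModel:
    """Least-squares (covariance-method) AR fit with FPE order selection.

    For each candidate order p in 1..p_max the one-step predictor is fitted
    on the N − p covariance-method equations; FPE(p) = σ̂²_p (N+p+1)/(N−p−1)
    with σ̂²_p = RSS/(N−p).  The order minimizing FPE is returned; all FPE
    values are kept for inspection in ``fpe_path``.
    """
    x = np.asarray(prestim, dtype=float)
    N = x.size
    if p_max >= N // 2:
        raise ValueError("p_max must be < len(prestim)/2")
    best = None
    fpe_path: dict[int, float] = {}
    for p in range(1, p_max + 1):
        cols = [x[p - k : N - k] for k in range(1, p + 1)]
        X = np.column_stack(cols)
        target = x[p:]
        try:
            a, *_ = np.linalg.lstsq(X, target, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            continue
        rss = float(np.sum((target - X @ a) ** 2))
        sigma2 = rss / (N - p)
        if sigma2 <= 0:
            sigma2 = max(rss, 1e-12) / (N - p)
        fpe = sigma2 * (N + p + 1) / (N - p - 1)
        fpe_path[p] = fpe
        if best is None or fpe < best[0]:
            best = (fpe, p, a, sigma2)
    if best is None:
        raise RuntimeError("AR fit failed at every candidate order")
    fpe, p, a, sigma2 = best
    a = _stabilize(a)
    return ARModel(p=p, coeffs=a, sigma2=max(sigma2, 1e-12), fpe=fpe, fpe_path=fpe_path)


def whitening_matrix(ar: ARModel, n: int) -> np.ndarray:
    """Lower-triangular banded Toeplitz whitener: unit diagonal, −a_k on the
    k-th subdiagonal, so A·v is approximately white with variance σ² when v
    follows the AR model.  Noise covariance is modeled as σ²(AᵀA)⁻¹."""
    A = np.eye(n)
    for k, a_k in enumerate(np.atleast_1d(ar.coeffs), start=1):
        if k >= n:
            break
        idx = np.arange(k, n)
        A[idx, idx - k] = -a_k
    return A


def difference_matrix(m: int, n: int) -> np.ndarray:
    """m-th discrete difference with zero initial conditions: the inverse of
    the m-fold cumulative sum, lower-triangular Toeplitz and invertible."""
    if m < 1:
        raise ValueError("m must be >= 1")
    D = np.eye(n)
    D[np.arange(1, n), np.arange(n - 1)] = -1.0
    F = np.eye(n)
    for _ in range(m):
        F = D @ F
    return F


def _lower_banded(M: np.ndarray, bw: int) -> np.ndarray:
    """Extract the lower-banded storage (scipy ``lower=True`` layout)."""
    n = M.shape[0]
    ab = np.zeros((bw + 1, n))
    for i in range(bw + 1):
        ab[i, : n - i] = np.diagonal(M, -i)
    return ab


class _EpochSmoother:
    """Precomputed banded operators for repeated solves at many γ values."""

    def __init__(self, y: np.ndarray, A: np.ndarray, F: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.A = A
        n = self.y.size
        AtA = A.T @ A
        FtF = F.T @ F
        self.bw = max(_bandwidth(AtA), _bandwidth(FtF))
        self.ata_b = _lower_banded(AtA, self.bw)
        self.ftf_b = _lower_banded(FtF, self.bw)
        self.rhs = AtA @ self.y

    def solve(self, gamma: float) -> np.ndarray:
        if gamma == 0.0:
            return self.y.copy()
        ab = self.ata_b + gamma * self.ftf_b
        return solveh_banded(ab, self.rhs, lower=True)

    def wrss(self, gamma: float) -> float:
        u = self.solve(gamma)
        r = self.A @ (self.y - u)
        return float(r @ r)


def _bandwidth(M: np.ndarray) -> int:
    n = M.shape[0]
    for bw in range(n - 1, 0, -1):
        if np.any(np.diagonal(M, -bw) != 0.0):
            return bw
    return 0


def smooth(y: np.ndarray, A: np.ndarray, F: np.ndarray, gamma: float) -> np.ndarray:
    """û = (AᵀA + γFᵀF)⁻¹ AᵀA y via a banded Cholesky solve.

    γ = 0 returns y exactly (the unregularized limit, AᵀA invertible).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("input contains non-finite values")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return _EpochSmoother(y, A, F).solve(gamma)


def wrss(y: np.ndarray, u_hat: np.ndarray, A: np.ndarray) -> float:
    """Whitened residual sum of squares (y−û)ᵀAᵀA(y−û) = ‖A(y−û)‖²."""
    r = A @ (np.asarray(y, float) - np.asarray(u_hat, float))
    return float(r @ r)


def tune_gamma_discrepancy(
    y: np.ndarray,
    A: np.ndarray,
    F: np.ndarray,
    sigma2: float,
    config: SmootherConfig = SmootherConfig(),
):
    """Find γ with WRSS(γ) = n·σ² by bisection on log10 γ.

    WRSS is nondecreasing in γ, so the root is bracketed whenever
    WRSS(γ_lo) ≤ n·σ² ≤ WRSS(γ_hi); otherwise the nearest bound is returned
    with ``converged=False`` (WRSS(γ_hi) < nσ²: even maximal smoothing leaves
    less residual energy than the noise model predicts — undersmoothed data).
    Returns ``(gamma, EstimatedERP)``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("input contains non-finite values")
    es = _EpochSmoother(y, A, F)
    n = y.size
    target = n * sigma2
    tol = config.discrepancy_rel_tol
    lo, hi = config.gamma_bounds
    w_lo, w_hi = es.wrss(lo), es.wrss(hi)

    def _result(gamma: float, w: float, converged: bool):
        erp = EstimatedERP(
            u_hat=es.solve(gamma), gamma=float(gamma),
            ar=ARModel(p=0, coeffs=np.empty(0), sigma2=sigma2, fpe=np.nan),
            wrss=float(w), converged=converged,
        )
        return float(gamma), erp

    if w_hi < target:
        return _result(hi, w_hi, False)
    if w_lo > target:
        return _result(lo, w_lo, False)
    llo, lhi = np.log10(lo), np.log10(hi)
    gamma, w = hi, w_hi
    for _ in range(config.max_iter):
        lmid = 0.5 * (llo + lhi)
        gamma = 10.0**lmid
        w = es.wrss(gamma)
        if abs(w - target) <= tol * target:
            return _result(gamma, w, True)
        if w < target:
            llo = lmid
        else:
            lhi = lmid
    return _result(gamma, w, abs(w - target) <= tol * target)


def calibrate_gamma_star(gammas) -> GammaStar:
    """γ* = median of per-epoch discrepancy-tuned γ values (targets and
    nontargets alike)."""
    g = np.asarray(list(gammas), dtype=float)
    if g.size == 0:
        raise ValueError("at least one calibration gamma required")
    return GammaStar(value=float(np.median(g)), n_calibration_epochs=int(g.size), source_gammas=g)


def estimate_single_trial(
    epoch: RawEpoch,
    config: SmootherConfig = SmootherConfig(),
    gamma_star: float | GammaStar | None = None,
) -> EstimatedERP:
    """Full single-trial stage for one epoch.

    Baseline-corrects, fits the AR noise model on the 100 prestimulus
    samples (FPE order selection), builds the whitening and difference
    operators on the 200 poststimulus samples, and smooths with either the
    per-epoch discrepancy-tuned γ (``gamma_star=None``, calibration mode) or
    the supplied fixed γ* (testing mode).
    """
    epoch = baseline_correct(epoch)
    ar = fit_ar_fpe(epoch.pre, p_max=config.p_max)
    n = epoch.post.size
    A = whitening_matrix(ar, n)
    F = difference_matrix(config.m, n)
    if gamma_star is None:
        gamma, erp = tune_gamma_discrepancy(epoch.post, A, F, ar.sigma2, config)
        return EstimatedERP(
            u_hat=erp.u_hat, gamma=gamma, ar=ar, wrss=erp.wrss,
            converged=erp.converged, mode="per_epoch_discrepancy", label=epoch.label,
        )
    gval = gamma_star.value if isinstance(gamma_star, GammaStar) else float(gamma_star)
    u_hat = smooth(epoch.post, A, F, gval)
    return EstimatedERP(
        u_hat=u_hat, gamma=gval, ar=ar, wrss=wrss(epoch.post, u_hat, A),
        converged=True, mode="fixed_gamma", label=epoch.label,
    )


class BayesianERPSmoother(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping the single-trial estimator.

    Rows of X are whole epochs (``n_pre`` prestimulus followed by
    poststimulus samples).  ``fit`` runs per-epoch discrepancy tuning on
    every row and stores γ* (the median); ``transform`` smooths new epochs
    with the fixed γ*.  ``fit_transform`` returns the per-epoch-γ estimates
    themselves, mirroring how calibration data are processed: calibration
    epochs are smoothed with their own optimal γ, test epochs with γ*.

    Parameters
    ----------
    n_pre : int
        Number of leading prestimulus samples per row (AR identification).
    m : int
        Order of the integrated-white-noise prior (2 = smooth ERP).
    p_max : int
        Upper bound of the FPE order search.
    gamma_bounds, discrepancy_rel_tol, max_iter
        Root-search settings of the discrepancy criterion.
    """

    def __init__(
        self,
        n_pre: int = N_PRE,
        m: int = 2,
        p_max: int = 10,
        gamma_bounds: tuple = (1e-4, 1e8),
        discrepancy_rel_tol: float = 1e-3,
        max_iter: int = 60,
    ):
        self.n_pre = n_pre
        self.m = m
        self.p_max = p_max
        self.gamma_bounds = gamma_bounds
        self.discrepancy_rel_tol = discrepancy_rel_tol
        self.max_iter = max_iter

    def _config(self) -> SmootherConfig:
        return SmootherConfig(
            m=self.m, p_max=self.p_max, gamma_bounds=tuple(self.gamma_bounds),
            discrepancy_rel_tol=self.discrepancy_rel_tol, max_iter=self.max_iter,
        )

    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] <= self.n_pre:
            raise ValueError(
                f"X must be 2-D with more than n_pre={self.n_pre} columns, got {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return baseline_correct_array(X, self.n_pre)

    def _estimate_row(self, row: np.ndarray, config: SmootherConfig, gamma=None):
        pre, post = row[: self.n_pre], row[self.n_pre :]
        ar = fit_ar_fpe(pre, p_max=self.p_max)
        A = whitening_matrix(ar, post.size)
        F = difference_matrix(self.m, post.size)
        if gamma is None:
            g, erp = tune_gamma_discrepancy(post, A, F, ar.sigma2, config)
            return g, erp.u_hat, erp.converged, ar
        return gamma, smooth(post, A, F, gamma), True, ar

    def fit(self, X, y=None):
        self._fit(X)
        return self

    def _fit(self, X) -> np.ndarray:
        X = self._validate(X)
        config = self._config()
        gammas, rows, conv = [], [], []
        for row in X:
            g, u, c, _ = self._estimate_row(row, config)
            gammas.append(g)
            rows.append(u)
            conv.append(c)
        self.n_features_in_ = X.shape[1]
        self.gammas_ = np.asarray(gammas)
        self.converged_ = np.asarray(conv)
        self.gamma_star_ = calibrate_gamma_star(self.gammas_).value
        return np.stack(rows)

    def fit_transform(self, X, y=None):
        # Calibration-mode output: each epoch smoothed with its own tuned γ.
        return self._fit(X)

    def transform(self, X):
        check_is_fitted(self, "gamma_star_")
        X = self._validate(X)
        config = self._config()
        return np.stack(
            [self._estimate_row(row, config, gamma=self.gamma_star_)[1] for row in X]
        )

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "n_features_in_")
        n_post = self.n_features_in_ - self.n_pre
        return np.asarray([f"erp{i}" for i in range(n_post)], dtype=object)
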