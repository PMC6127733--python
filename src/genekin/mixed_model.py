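"""Single-kernel linear mixed model: REML, BLUP, phenotype pre-adjustment.

The model is y = X b + Z g + e with g ~ N(0, K sigma2_g) for a given
relatedness kernel K and e ~ N(0, I sigma2_e).  Variance components are
estimated by restricted maximum likelihood, profiled over the variance
ratio delta = sigma2_g / sigma2_e: projecting y onto the orthogonal
complement of the fixed-effect column space and eigendecomposing the
projected kernel once reduces REML to a bounded one-dimensional search
in log(delta), with sigma2_e available in closed form at each delta.
Predictions for unobserved individuals use the kernel cross-block:
g_test = K[test, train] (K[train, train] + lambda I)^(-1) (y - X b),
lambda = sigma2_e / sigma2_g.

:class:`KernelGBLUP` wraps this as a scikit-learn-style estimator over a
precomputed kernel (``fit(K, y)``; ``predict(K_cross)``); the module
functions are thin wrappers over it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .similarity_kernels import RelatednessMatrix

logger = logging.getLogger(__name__)

_LOG_DELTA_BOUNDS = (-25.0, 25.0)
_PSD_CLIP_REL = 1e-6  # eigenvalues above -clip*max are clipped to zero


def _as_kernel_array(K) -> np.ndarray:
    if isinstance(K, RelatednessMatrix):
        return np.asarray(K.values, dtype=float)
    return np.asarray(K, dtype=float)


def _psd_repair(K: np.ndarray, enabled: bool) -> np.ndarray:
    """Clip slightly negative eigenvalues; jitter more negative ones.

    Similarity kernels carry no positive-semidefiniteness guarantee, so
    small negative eigenvalues are expected numerical debris while large
    ones are repaired by the minimal diagonal shift (and logged).
    """
    eigvals = linalg.eigvalsh(K)
    lo, hi = eigvals[0], eigvals[-1]
    if lo >= 0:
        return K
    if not enabled:
        raise ValueError(
            f"kernel has negative eigenvalue {lo:.3e} and PSD repair is disabled"
        )
    if lo > -_PSD_CLIP_REL * max(hi, 1.0):
        vals, vecs = linalg.eigh(K)
        return (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    logger.info("adding diagonal jitter %.3e to indefinite kernel", -lo)
    return K + (-lo) * np.eye(K.shape[0])


class KernelGBLUP(RegressorMixin, BaseEstimator):
    """GBLUP with a precomputed relatedness kernel, fitted by REML.

    Parameters
    ----------
    psd_repair : bool, default True
        Repair indefinite kernels by eigenvalue clipping / diagonal
        jitter before fitting; if False, an indefinite kernel is an error.
    tol : float, default 1e-8
        Convergence tolerance of the bounded scalar search in log(delta).

    Attributes
    ----------
    sigma2_g_, sigma2_e_ : float
        REML variance components (non-negative; boundary solutions allowed).
    beta_ : ndarray
        Generalized-least-squares fixed-effect estimates.
    ghat_ : ndarray
        BLUP genetic values of the training individuals.
    loglik_ : float
        Attained restricted log-likelihood (error-contrast form).
    converged_ : bool
    boundary_ : bool
        True when a variance component sits on the zero boundary.
    h2_ : float
        sigma2_g_ / (sigma2_g_ + sigma2_e_).

    Examples
    --------
    >>> model = KernelGBLUP().fit(K_train, y_train)
    >>> g_new = model.predict(K_new_vs_train)
    """

    def __init__(self, psd_repair: bool = True, tol: float = 1e-8):
        self.psd_repair = psd_repair
        self.tol = tol

    # -- restricted likelihood machinery -------------------------------

    @staticmethod
    def _project(X: np.ndarray) -> np.ndarray:
        """Orthonormal basis of the complement of col(X)."""
        n, p = X.shape
        Q, R = np.linalg.qr(X, mode="complete")
        if np.linalg.matrix_rank(R[:p, :p]) < p:
            raise ValueError("fixed-effect design X is rank deficient")
        return Q[:, p:]

    def fit(self, K, y, X=None):
        """Fit variance components and BLUPs on the training kernel.

        Parameters
        ----------
        K : (n, n) array or RelatednessMatrix
            Kernel among the training individuals.
        y : (n,) array
            Response (phenotypes, possibly pre-adjusted).
        X : (n, p) array, optional
            Fixed-effect design; defaults to an intercept column.
        """
        K = _as_kernel_array(K)
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if K.shape != (n, n):
            raise ValueError(f"kernel shape {K.shape} does not match n={n}")
        if n < 3:
            raise ValueError("need at least 3 observations for REML")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")
        if np.var(y) <= 0:
            raise ValueError("zero phenotypic variance in y")
        if X is None:
            X = np.ones((n, 1))
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]

        K = _psd_repair(K, self.psd_repair)
        A = self._project(X)
        Kt = A.T @ K @ A
        d, U = linalg.eigh(Kt)
        d = np.clip(d, 0.0, None)  # projection of a PSD kernel stays PSD
        w = U.T @ (A.T @ y)
        m = d.size  # n - p error contrasts

        if d[-1] - d[0] < 1e-8 * max(d[-1], 1.0):
            warnings.warn(
                "projected kernel is numerically proportional to the identity; "
                "genetic and residual variance are not separately identifiable "
                "(restricted likelihood is flat in the ratio)",
                UserWarning,
            )

        def neg_rll(log_delta: float) -> float:
            v = np.exp(log_delta) * d + 1.0
            s2e = (w**2 / v).sum() / m
            return 0.5 * (m * (np.log(2 * np.pi * s2e) + 1.0) + np.log(v).sum())

        lo, hi = _LOG_DELTA_BOUNDS
        res = optimize.minimize_scalar(
            neg_rll, bounds=(lo, hi), method="bounded", options={"xatol": self.tol}
        )
        candidates = [(neg_rll(lo), lo), (neg_rll(hi), hi), (res.fun, res.x)]
        fun, log_delta = min(candidates, key=lambda t: t[0])

        boundary = False
        delta = float(np.exp(log_delta))
        if log_delta <= lo + 1e-9:
            delta, boundary = 0.0, True
        elif log_delta >= hi - 1e-9:
            boundary = True
        v = delta * d + 1.0
        sigma2_e = float((w**2 / v).sum() / m)
        sigma2_g = delta * sigma2_e
        if delta > 0 and sigma2_e < 1e-12 * max(sigma2_g, 1.0):
            boundary = True

        # GLS fixed effects and training BLUPs at the fitted components
        V = sigma2_g * K + sigma2_e * np.eye(n)
        Vinv_y = linalg.solve(V, y, assume_a="pos")
        Vinv_X = linalg.solve(V, X, assume_a="pos")
        beta = linalg.solve(X.T @ Vinv_X, X.T @ Vinv_y, assume_a="pos")
        resid = y - X @ beta
        ghat = sigma2_g * (K @ linalg.solve(V, resid, assume_a="pos"))

        self.n_features_in_ = n
        self.K_ = K
        self.X_ = X
        self.y_ = y
        self.sigma2_g_ = max(sigma2_g, 0.0)
        self.sigma2_e_ = max(sigma2_e, 0.0)
        self.beta_ = beta
        self.resid_ = resid
        self.ghat_ = ghat
        self.loglik_ = -fun
        self.converged_ = bool(res.success or boundary)
        self.boundary_ = boundary
        total = self.sigma2_g_ + self.sigma2_e_
        self.h2_ = self.sigma2_g_ / total if total > 0 else 0.0
        if self.sigma2_g_ > 0:
            lam = self.sigma2_e_ / self.sigma2_g_
            self.alpha_ = linalg.solve(
                K + lam * np.eye(n) + 1e-12 * np.eye(n), resid, assume_a="sym"
            )
        else:
            self.alpha_ = np.zeros(n)
        return self

    def predict(self, K_cross) -> np.ndarray:
        """Predict genetic values from the (n_new, n_train) kernel block."""
        if not hasattr(self, "alpha_"):
            raise ValueError("KernelGBLUP instance is not fitted yet")
        K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
        if K_cross.shape[1] != self.n_features_in_:
            raise ValueError(
                f"cross-kernel has {K_cross.shape[1]} columns, expected "
                f"{self.n_features_in_} (training individuals)"
            )
        if self.sigma2_g_ == 0.0:
            return np.zeros(K_cross.shape[0])
        return K_cross @ self.alpha_


@dataclass
class MixedModelSpec:
    """Inputs of one mixed-model fit (response, fixed design, kernel, Z)."""

    y: np.ndarray
    K: RelatednessMatrix | np.ndarray
    X: np.ndarray | None = None
    Z: np.ndarray | None = None  # observation -> individual incidence


@dataclass
class FitResult:
    """REML variance components, fixed effects and BLUP genetic values."""

    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray
    ghat: np.ndarray
    reml_loglik: float
    converged: bool
    boundary: bool
    residuals: np.ndarray = field(repr=False, default=None)
    individual_ids: list[str] | None = None

    @property
    def h2(self) -> float:
        total = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / total if total > 0 else 0.0

    @property
    def ratio(self) -> float:
        """lambda = sigma2_e / sigma2_g (inf at the zero-genetic boundary)."""
        return self.sigma2_e / self.sigma2_g if self.sigma2_g > 0 else np.inf


def reml_fit(spec: MixedModelSpec, psd_repair: bool = True, tol: float = 1e-8) -> FitResult:
    """REML fit of the single-kernel mixed model (see module docstring).

    With an observation-level incidence ``Z`` the fit runs on the
    observation kernel Z K Z' and genetic values are recovered for every
    individual in K.
    """
    K = _as_kernel_array(spec.K)
    ids = spec.K.individual_ids if isinstance(spec.K, RelatednessMatrix) else None
    y = np.asarray(spec.y, dtype=float).ravel()
    Z = spec.Z
    model = KernelGBLUP(psd_repair=psd_repair, tol=tol)
    if Z is None:
        model.fit(K, y, X=spec.X)
        ghat = model.ghat_
    else:
        Z = np.asarray(Z, dtype=float)
        model.fit(Z @ K @ Z.T, y, X=spec.X)
        # individual-level BLUPs: g = sigma2_g K Z' V^{-1} (y - X beta)
        V = model.sigma2_g_ * (Z @ K @ Z.T) + model.sigma2_e_ * np.eye(y.size)
        ghat = model.sigma2_g_ * (K @ Z.T @ linalg.solve(V, model.resid_, assume_a="pos"))
    return FitResult(
        sigma2_g=model.sigma2_g_,
        sigma2_e=model.sigma2_e_,
        beta=model.beta_,
        ghat=ghat,
        reml_loglik=model.loglik_,
        converged=model.converged_,
        boundary=model.boundary_,
        residuals=model.resid_,
        individual_ids=ids,
    )


def blup_predict(
    fit: FitResult,
    K_full: RelatednessMatrix,
    train_ids: list[str],
    test_ids: list[str],
) -> np.ndarray:
    """Predict genetic values of unobserved individuals from a fitted model.

    g_test = K[test, train] (K[train, train] + lambda I)^(-1) (y - X b)
    with lambda = sigma2_e / sigma2_g; all zeros when sigma2_g = 0.
    """
    if fit.sigma2_g <= 0:
        return np.zeros(len(test_ids))
    K_tt = K_full.restrict(train_ids)
    K_xt = K_full.restrict(test_ids, train_ids)
    lam = fit.sigma2_e / fit.sigma2_g
    n = K_tt.shape[0]
    try:
        sol = linalg.solve(K_tt + lam * np.eye(n), fit.residuals, assume_a="sym")
    except linalg.LinAlgError:
        sol = linalg.solve(
            K_tt + (lam + 1e-8) * np.eye(n), fit.residuals, assume_a="sym"
        )
    return K_xt @ sol


def adjust_phenotypes(
    y: np.ndarray, X: np.ndarray, G: RelatednessMatrix | np.ndarray
) -> np.ndarray:
    """Pre-adjust phenotypes for fixed effects under a genomic kernel.

    Fits y = X b + u + e with u ~ N(0, G sigma2_u) by REML, estimates b
    by generalized least squares at the fitted variance components, and
    returns the adjusted response y - X b.
    """
    spec = MixedModelSpec(y=np.asarray(y, float), K=G, X=np.asarray(X, float))
    fit = reml_fit(spec)
    return fit.residuals
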