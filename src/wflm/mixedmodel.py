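"""Null polygenic model and GLS whitening for structured samples.

The trait model is y = X alpha + h + e with h ~ N(0, sigma_g^2 R) and
e ~ N(0, sigma_e^2 I), so Omega = sigma_g^2 R + sigma_e^2 I. R is the
expected additive (numerator) relationship matrix — twice the kinship,
diagonal 1 for outbred individuals — and the identity for unrelated samples.

Variance components are estimated by REML, profiled over the heritability
h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2): after rotating by the eigenvectors
of R = U D U^T, Omega becomes diagonal and the restricted likelihood is a
cheap 1-D function of h2, maximized by bounded scalar search. The fitted
object supplies the whitening transform Omega^(-1/2) used by the region
F-test; components are estimated once under the null (no region term) and
held fixed across regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["PhenotypeData", "RelationshipMatrix", "NullModelFit", "fit_null", "decorrelate"]

_H2_TOL = 1e-8


@dataclass
class PhenotypeData:
    """Trait vector and covariate matrix (leading intercept column)."""

    ids: np.ndarray
    y: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.size
        if self.X.shape[0] != n or self.ids.size != n:
            raise ValueError("ids, y and X must agree on the number of samples")
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.X)):
            raise ValueError("missing values must be dropped before model fitting")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be the intercept")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("covariate matrix X is rank deficient")

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class RelationshipMatrix:
    """Symmetric PSD expected additive relationship matrix with sample IDs."""

    R: np.ndarray
    ids: np.ndarray

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.ids = np.asarray(self.ids)
        n = self.ids.size
        if self.R.shape != (n, n):
            raise ValueError("R must be square and conformable with ids")
        if np.max(np.abs(self.R - self.R.T)) > 1e-10:
            raise ValueError("relationship matrix is not symmetric")
        self.R = 0.5 * (self.R + self.R.T)
        self._eig = None

    def eigendecomposition(self):
        """Cached R = U diag(d) U^T with eigenvalues clipped at zero."""
        if self._eig is None:
            d, U = np.linalg.eigh(self.R)
            if d.min() < -1e-8:
                raise ValueError(
                    f"relationship matrix has eigenvalue {d.min():.3g} < -1e-8; not PSD"
                )
            self._eig = (U, np.clip(d, 0.0, None))
        return self._eig

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.max(np.abs(self.R - np.eye(self.R.shape[0]))) < tol)


@dataclass
class NullModelFit:
    """REML fit of the null polygenic model; holds the whitening ingredients."""

    alpha_hat: np.ndarray
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    eigvecs: np.ndarray | None  # None encodes U = I (unrelated fast path)
    eigvals: np.ndarray
    n: int
    p: int

    @property
    def sigma2(self) -> float:
        return self.sigma_g2 + self.sigma_e2


def _reml_profile(h2: float, y_t: np.ndarray, X_t: np.ndarray, d: np.ndarray):
    """Restricted log-likelihood (up to constants) at heritability h2.

    Inputs are already rotated into the eigenbasis of R, so the covariance is
    sigma^2 diag(h2 d + 1 - h2) and sigma^2 profiles out analytically.
    """
    n, p = X_t.shape
    lam = h2 * d + (1.0 - h2)
    if np.any(lam <= 0):
        return -np.inf, None, None
    sw = 1.0 / np.sqrt(lam)
    Xw = X_t * sw[:, None]
    yw = y_t * sw
    coef, _, rank, sv = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        return -np.inf, None, None
    r = yw - Xw @ coef
    rss = float(r @ r)
    sigma2 = rss / (n - p)
    ll = -0.5 * (
        (n - p) * np.log(sigma2)
        + np.log(lam).sum()
        + 2.0 * np.log(sv[:rank]).sum()
        + (n - p)
    )
    return float(ll), coef, sigma2


def _fit_rotated(y_t: np.ndarray, X_t: np.ndarray, d: np.ndarray):
    """Profile REML over h2 in [0, 1): returns (h2, sigma2, alpha, loglik)."""
    res = optimize.minimize_scalar(
        lambda h: -_reml_profile(h, y_t, X_t, d)[0],
        bounds=(0.0, 1.0 - 1e-6),
        method="bounded",
        options={"xatol": _H2_TOL},
    )
    h2 = float(res.x)
    # snap to the boundary when the optimizer sits within tolerance of it
    for bound in (0.0, 1.0 - 1e-6):
        if abs(h2 - bound) < 10 * _H2_TOL and _reml_profile(bound, y_t, X_t, d)[0] >= -res.fun:
            h2 = bound
    ll, coef, sigma2 = _reml_profile(h2, y_t, X_t, d)
    return h2, sigma2, coef, ll


def fit_null(data: PhenotypeData, R: RelationshipMatrix | None = None) -> NullModelFit:
    """REML-fit the null model y = X alpha + h + e.

    With R = I (or R omitted) the variance components are unidentifiable and
    the convention sigma_g2 = 0, sigma_e2 = total residual variance, h2 = 0
    is reported; the model is then ordinary least squares.
    """
    y, X = data.y, data.X
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than samples in the null model")
    if np.var(y) == 0:
        raise ValueError("trait has zero variance")

    if R is None or R.is_identity():
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        sigma2 = float(r @ r) / (n - p)
        ll, _, _ = _reml_profile(0.0, y, X, np.ones(n))
        return NullModelFit(coef, 0.0, sigma2, 0.0, ll, None, np.ones(n), n, p)

    if R.ids.size != n:
        raise ValueError("relationship matrix is not conformable with the phenotype data")
    U, d = R.eigendecomposition()
    y_t = U.T @ y
    X_t = U.T @ X
    h2, sigma2, coef, ll = _fit_rotated(y_t, X_t, d)
    return NullModelFit(coef, h2 * sigma2, (1.0 - h2) * sigma2, h2, ll, U, d, n, p)


def decorrelate(fit: NullModelFit, M: np.ndarray) -> np.ndarray:
    """Whiten columns of M by Omega^(-1/2) through the stored eigendecomposition."""
    M = np.asarray(M, dtype=float)
    lam = fit.sigma_g2 * fit.eigvals + fit.sigma_e2
    if np.any(lam <= 0):
        raise ValueError("Omega is singular; cannot whiten")
    sw = 1.0 / np.sqrt(lam)
    if fit.eigvecs is None:
        return M * sw[0] if np.ptp(lam) == 0 else (M.T * sw).T
    Mt = fit.eigvecs.T @ M
    Mt = (Mt.T * sw).T
    return fit.eigvecs @ Mt
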