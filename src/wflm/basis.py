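"""Basis-function machinery for functional smoothing of genotypes and effects.

A genomic region with variants at physical positions t_1 < ... < t_m is mapped
onto [0, 1]. Genotypes along the region (one curve per individual) and the
effect-size curve beta(t) are each expanded in a finite basis — cubic
B-splines on uniform knots, or an orthonormal Fourier system. The two
expansions combine into the m x K_beta smoother matrix

    W = Phi (Phi^T Phi)^{-1} J,      J = int_0^1 phi(t) psi(t)^T dt,

which converts the raw n x m dosage design into an n x K_beta functional
design G W. When only the effect curve is smoothed ("beta-smooth only"),
W is simply the effect-basis evaluation matrix Psi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "PositionMap",
    "BasisSpec",
    "SmootherMatrix",
    "scale_positions",
    "fourier_basis",
    "bspline_basis",
    "evaluate_basis",
    "cross_integral",
    "build_smoother",
]

# jitter step (in scaled units) separating duplicate positions
_DUP_EPS = 1e-6


@dataclass(frozen=True)
class PositionMap:
    """Variant positions of one region, raw and affinely scaled to [0, 1]."""

    raw: np.ndarray
    scaled: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "raw", np.asarray(self.raw))
        object.__setattr__(self, "scaled", np.asarray(self.scaled, dtype=float))
        if self.raw.shape != self.scaled.shape or self.raw.ndim != 1:
            raise ValueError("raw and scaled positions must be equal-length 1-D arrays")

    @property
    def m(self) -> int:
        return self.raw.size


@dataclass(frozen=True)
class BasisSpec:
    """A basis family on [0, 1]: 'bspline' (with order) or 'fourier'.

    For B-splines, K is the number of basis functions and `order` the spline
    order (4 = cubic); the knot vector has order-fold boundary knots at 0 and
    1 and K - order equally spaced interior knots. For Fourier, K must be odd:
    the constant plus (K-1)/2 sine/cosine pairs, orthonormal on [0, 1].
    """

    family: str
    K: int
    order: int = 4

    def __post_init__(self):
        if self.family not in ("bspline", "fourier"):
            raise ValueError(f"unknown basis family {self.family!r}")
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        if self.family == "fourier" and self.K % 2 == 0:
            raise ValueError("Fourier basis requires odd K (constant + sin/cos pairs)")
        if self.family == "bspline":
            if self.order < 1:
                raise ValueError("spline order must be >= 1")
            if self.K < self.order:
                raise ValueError(f"B-spline basis needs K >= order ({self.K} < {self.order})")

    def reduce_to(self, m: int) -> "BasisSpec":
        """Largest valid basis of this family with K <= m (overparametrization guard)."""
        if self.K <= m:
            return self
        if self.family == "fourier":
            k = m if m % 2 == 1 else m - 1
            if k < 1:
                raise ValueError(f"cannot fit a Fourier basis to {m} variants")
        else:
            k = m
            if k < self.order:
                raise ValueError(
                    f"cannot fit an order-{self.order} B-spline basis to {m} variants"
                )
        return BasisSpec(self.family, k, self.order)

    def knots(self) -> np.ndarray:
        if self.family != "bspline":
            raise ValueError("knots are defined for B-spline bases only")
        interior = np.linspace(0.0, 1.0, self.K - self.order + 2)[1:-1]
        return np.concatenate([np.zeros(self.order), interior, np.ones(self.order)])

    def breakpoints(self) -> np.ndarray:
        """Subdivision of [0, 1] on which this basis is smooth/well-resolved."""
        if self.family == "bspline":
            return np.linspace(0.0, 1.0, self.K - self.order + 2)
        # enough intervals that 7-point Gauss-Legendre integrates the highest
        # frequency to ~1e-14 per interval
        k_max = (self.K - 1) // 2
        return np.linspace(0.0, 1.0, 2 * k_max + 2)


@dataclass(frozen=True)
class SmootherMatrix:
    """Evaluated bases and the smoother W for one region.

    Phi is the m x K_G genotype-basis matrix (None on the beta-smooth-only
    path), Psi the m x K_beta effect-basis matrix, J the K_G x K_beta
    cross-integral, and W the m x K_beta smoother.
    """

    Phi: np.ndarray | None
    Psi: np.ndarray
    J: np.ndarray | None
    W: np.ndarray
    genotype_spec: BasisSpec | None
    effect_spec: BasisSpec
    notes: tuple[str, ...] = field(default=())

    @property
    def K_beta(self) -> int:
        return self.W.shape[1]


def scale_positions(raw_positions) -> PositionMap:
    """Affinely map base-pair positions onto [0, 1].

    Positions are sorted ascending; exact duplicates are separated by a
    deterministic jitter of +k * 1e-6 (k = occurrence index within the tied
    group, scaled units) so that basis arguments are distinct, then the map
    is renormalized to keep the endpoints at exactly 0 and 1.
    """
    raw = np.sort(np.asarray(raw_positions))
    if raw.size < 2:
        raise ValueError("a region needs at least 2 variants to define a position scale")
    span = float(raw[-1] - raw[0])
    if span <= 0:
        raise ValueError("all variant positions are identical: degenerate region")
    scaled = (raw - raw[0]) / span
    # deterministic jitter for ties
    if np.any(np.diff(scaled) == 0):
        scaled = scaled.copy()
        _, inverse, counts = np.unique(scaled, return_inverse=True, return_counts=True)
        if np.any(counts > 1):
            occ = np.zeros_like(scaled)
            for g in np.flatnonzero(counts > 1):
                idx = np.flatnonzero(inverse == g)
                occ[idx] = np.arange(idx.size)
            scaled = scaled + occ * _DUP_EPS
            scaled = (scaled - scaled[0]) / (scaled[-1] - scaled[0])
        if np.any(np.diff(scaled) <= 0):
            raise ValueError("duplicate-position jitter failed to separate positions")
    return PositionMap(raw=raw, scaled=scaled)


def fourier_basis(t, K: int) -> np.ndarray:
    """Orthonormal Fourier basis on [0, 1]: [1, sqrt2 sin(2*pi*t), sqrt2 cos(2*pi*t), ...]."""
    if K < 1 or K % 2 == 0:
        raise ValueError("Fourier basis requires odd K >= 1")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty((t.size, K))
    out[:, 0] = 1.0
    sqrt2 = np.sqrt(2.0)
    for k in range(1, (K - 1) // 2 + 1):
        w = 2.0 * np.pi * k * t
        out[:, 2 * k - 1] = sqrt2 * np.sin(w)
        out[:, 2 * k] = sqrt2 * np.cos(w)
    return out


def bspline_basis(t, K: int, order: int = 4) -> np.ndarray:
    """B-spline basis on [0, 1] with uniform interior knots; rows sum to 1."""
    spec = BasisSpec("bspline", K, order)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("B-spline basis arguments must lie in [0, 1]")
    return BSpline.design_matrix(t, spec.knots(), order - 1, extrapolate=False).toarray()


def evaluate_basis(t, spec: BasisSpec) -> np.ndarray:
    if spec.family == "fourier":
        return fourier_basis(t, spec.K)
    return bspline_basis(t, spec.K, spec.order)


def cross_integral(genotype_spec: BasisSpec, effect_spec: BasisSpec) -> np.ndarray:
    """J = int_0^1 phi(t) psi(t)^T dt, K_G x K_beta.

    Fourier x Fourier is analytic (orthonormality gives a truncated identity);
    any combination involving B-splines uses composite 7-point Gauss-Legendre
    quadrature on the union of both bases' breakpoints, exact for the
    piecewise-polynomial parts and ~1e-14 accurate for the trigonometric ones.
    """
    if genotype_spec.family == "fourier" and effect_spec.family == "fourier":
        return np.eye(genotype_spec.K, effect_spec.K)
    brk = np.unique(np.concatenate([genotype_spec.breakpoints(), effect_spec.breakpoints()]))
    nodes, wts = np.polynomial.legendre.leggauss(7)
    a, b = brk[:-1], brk[1:]
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    # all quadrature points at once: intervals x nodes
    tq = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
    wq = (half[:, None] * wts[None, :]).ravel()
    Phi_q = evaluate_basis(tq, genotype_spec)
    Psi_q = evaluate_basis(tq, effect_spec)
    return Phi_q.T @ (Psi_q * wq[:, None])


def build_smoother(
    pos: PositionMap,
    genotype_spec: BasisSpec | None,
    effect_spec: BasisSpec,
) -> SmootherMatrix:
    """Assemble the smoother matrix W for one region.

    With a genotype basis, W = Phi (Phi^T Phi)^{-1} J (full smoothing); with
    genotype_spec=None, the beta-smooth-only path returns W = Psi. Basis sizes
    larger than the number of variants are reduced to the largest valid K <= m
    and the reduction recorded in `notes`.
    """
    m = pos.m
    notes: list[str] = []
    eff = effect_spec.reduce_to(m)
    if eff.K != effect_spec.K:
        notes.append(f"K_beta reduced {effect_spec.K}->{eff.K} (m={m})")
    Psi = evaluate_basis(pos.scaled, eff)

    if genotype_spec is None:
        return SmootherMatrix(None, Psi, None, Psi, None, eff, tuple(notes))

    gen = genotype_spec.reduce_to(m)
    if gen.K != genotype_spec.K:
        notes.append(f"K_G reduced {genotype_spec.K}->{gen.K} (m={m})")
    Phi = evaluate_basis(pos.scaled, gen)
    gram = Phi.T @ Phi
    J = cross_integral(gen, eff)
    try:
        c, low = _chol(gram)
        from scipy.linalg import cho_solve

        W = Phi @ cho_solve((c, low), J)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "Phi^T Phi is singular for this region (too few distinct positions "
            "for the genotype basis); use the beta-smooth-only path "
            "(genotype_spec=None) or a smaller K_G"
        ) from err
    return SmootherMatrix(Phi, Psi, J, W, gen, eff, tuple(notes))


def _chol(a: np.ndarray):
    from scipy.linalg import cho_factor, LinAlgError

    try:
        return cho_factor(a)
    except LinAlgError as err:  # normalize exception type
        raise np.linalg.LinAlgError(str(err)) from err
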