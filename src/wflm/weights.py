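"""Variant weighting by minor-allele frequency and MAF filtering.

Rare variants are, a priori, more likely to be deleterious, so region tests
upweight them. Weights come from the beta density evaluated at each variant's
MAF: shapes (1, 1) give the unweighted model, (1, 25) strongly favour rare
variants (the kernel-test standard), and (0.5, 0.5) is the arcsine density
that keeps growing as MAF -> 0. The weights form an m x m diagonal matrix
Theta that multiplies the genotype columns of the functional design G Theta W.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = ["WeightSpec", "WeightMatrix", "beta_weights", "weight_vector", "maf_filter"]


@dataclass(frozen=True)
class WeightSpec:
    """Beta-density weighting parameters, or explicit per-variant weights.

    The literature writes sqrt(w_j) = Beta(MAF_j; a1, a2) while the weighted
    design multiplies genotypes by Theta once; `convention` selects whether
    Theta_jj is the density itself ("density", default) or its square
    ("squared_density").
    """

    a1: float = 1.0
    a2: float = 25.0
    convention: str = "density"
    custom_weights: np.ndarray | None = None

    def __post_init__(self):
        if self.custom_weights is not None:
            w = np.asarray(self.custom_weights, dtype=float)
            if w.ndim != 1 or np.any(w < 0) or not np.all(np.isfinite(w)):
                raise ValueError("custom weights must be finite nonnegative 1-D")
            object.__setattr__(self, "custom_weights", w)
            return
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("beta shape parameters must be positive")
        if self.convention not in ("density", "squared_density"):
            raise ValueError(f"unknown weight convention {self.convention!r}")

    @classmethod
    def unweighted(cls) -> "WeightSpec":
        return cls(1.0, 1.0)


@dataclass(frozen=True)
class WeightMatrix:
    """Diagonal variant-weight matrix Theta, stored as its diagonal."""

    theta: np.ndarray

    def __post_init__(self):
        th = np.asarray(self.theta, dtype=float)
        if th.ndim != 1 or np.any(th < 0) or not np.all(np.isfinite(th)):
            raise ValueError("Theta diagonal must be finite and nonnegative")
        object.__setattr__(self, "theta", th)

    def as_matrix(self) -> np.ndarray:
        return np.diag(self.theta)


def beta_weights(mafs, a1: float, a2: float) -> WeightMatrix:
    """Theta_jj = Beta-pdf(MAF_j; a1, a2) = MAF^(a1-1) (1-MAF)^(a2-1) / B(a1, a2)."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]; remove monomorphic variants first")
    if a1 <= 0 or a2 <= 0:
        raise ValueError("beta shape parameters must be positive")
    # closed form keeps the (1, 1) case exactly 1.0 (x**0 == 1.0)
    w = mafs ** (a1 - 1.0) * (1.0 - mafs) ** (a2 - 1.0) / special.beta(a1, a2)
    return WeightMatrix(w)


def weight_vector(spec: WeightSpec | None, mafs) -> np.ndarray:
    """Per-variant weight diagonal for a spec (None means unweighted)."""
    mafs = np.asarray(mafs, dtype=float)
    if spec is None:
        return np.ones(mafs.size)
    if spec.custom_weights is not None:
        if spec.custom_weights.size != mafs.size:
            raise ValueError("custom weights length does not match number of variants")
        return spec.custom_weights
    if (spec.a1, spec.a2) == (1.0, 1.0):
        return np.ones(mafs.size)  # exact unweighted model
    w = beta_weights(mafs, spec.a1, spec.a2).theta
    if spec.convention == "squared_density":
        w = w * w
    return w


def maf_filter(region, threshold: float):
    """Restrict a region to variants with MAF <= threshold.

    Mirrors the filtering technique in which common variants are excluded
    before testing; positions are re-scaled downstream from the retained set.
    """
    if not (0 < threshold <= 0.5):
        raise ValueError("MAF threshold must lie in (0, 0.5]")
    keep = np.asarray(region.mafs) <= threshold
    if not keep.any():
        raise ValueError(f"no variant has MAF <= {threshold}: empty region")
    return dataclasses.replace(
        region,
        positions=np.asarray(region.positions)[keep],
        G=np.asarray(region.G)[:, keep],
        mafs=np.asarray(region.mafs)[keep],
    )
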