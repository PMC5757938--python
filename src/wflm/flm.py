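"""Weighted functional linear model F-test for one genomic region.

The region design is G Theta W: dosage matrix G (minor-allele counts),
diagonal MAF weights Theta, and smoother W built from the basis expansions of
the genotype and effect curves. The null H0: beta_F = 0 is tested with the
fixed-effects F-statistic of the mixed model — all of y, X and G Theta W are
whitened by Omega^(-1/2) from the null polygenic fit, after which the test is
an ordinary nested-model comparison:

    F = [(RSS0 - RSS1) / q] / [RSS1 / (n - p0 - q)],

with q the numerical rank of the whitened region design after projecting out
the covariates, so rank deficiencies induced by weighting or smoothing reduce
the numerator degrees of freedom instead of corrupting the test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats

from .basis import BasisSpec, build_smoother, scale_positions
from .mixedmodel import NullModelFit, PhenotypeData, decorrelate
from .weights import WeightSpec, weight_vector

__all__ = ["RegionGenotypes", "AssociationResult", "flm_test", "rank_guard"]

_RANK_RTOL = 1e-9


@dataclass
class RegionGenotypes:
    """Dosage matrix and variant metadata for one region.

    G holds minor-allele counts (n x m), columns aligned with sorted
    `positions`; `mafs` are sample minor-allele frequencies in (0, 0.5].
    Use `from_dosages` to build from raw (possibly major-allele-coded,
    possibly missing) dosages.
    """

    ids: np.ndarray
    positions: np.ndarray
    G: np.ndarray
    mafs: np.ndarray
    region_id: str = "region"

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.positions = np.asarray(self.positions)
        self.G = np.asarray(self.G, dtype=float)
        self.mafs = np.asarray(self.mafs, dtype=float)
        n, m = self.G.shape
        if self.ids.size != n:
            raise ValueError("ids do not match the rows of G")
        if self.positions.size != m or self.mafs.size != m:
            raise ValueError("positions/mafs do not match the columns of G")
        if m and np.any(np.diff(self.positions) < 0):
            raise ValueError("variant positions must be sorted ascending")
        if m and (np.any(self.mafs <= 0) or np.any(self.mafs > 0.5)):
            raise ValueError("MAFs must lie in (0, 0.5]: drop monomorphic variants")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def m(self) -> int:
        return self.G.shape[1]

    @classmethod
    def from_dosages(cls, ids, positions, G, region_id="region"):
        """Build a clean region from raw 0/1/2 dosages.

        Missing entries (NaN) are mean-imputed per variant, columns are
        re-polarized so dosages count the minor allele in this sample,
        monomorphic variants are dropped, and variants sorted by position.
        """
        G = np.array(G, dtype=float)
        positions = np.asarray(positions)
        if G.ndim != 2 or positions.size != G.shape[1]:
            raise ValueError("positions do not match the columns of G")
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        G = G[:, order]
        # mean imputation preserves the allele frequency
        if np.isnan(G).any():
            col_mean = np.nanmean(G, axis=0)
            idx = np.where(np.isnan(G))
            G[idx] = col_mean[idx[1]]
        p = G.mean(axis=0) / 2.0
        flip = p > 0.5
        G[:, flip] = 2.0 - G[:, flip]
        maf = np.where(flip, 1.0 - p, p)
        poly = (maf > 0) & (G.std(axis=0) > 0)
        if not poly.any():
            raise ValueError(f"region {region_id!r} has no polymorphic variants")
        return cls(ids, positions[poly], G[:, poly], maf[poly], region_id)


@dataclass
class AssociationResult:
    """F-test outcome for one region."""

    region_id: str
    n: int
    m_variants: int
    K_beta_used: int
    rank_used: int
    F_stat: float
    df1: int
    df2: int
    p_value: float
    beta_F_hat: np.ndarray | None = None
    notes: tuple[str, ...] = field(default=())

    def __post_init__(self):
        expected = float(stats.f.sf(self.F_stat, self.df1, self.df2))
        if not np.isclose(self.p_value, expected, rtol=1e-12, atol=1e-300):
            raise ValueError("p_value inconsistent with (F, df1, df2)")


def rank_guard(design: np.ndarray):
    """Numerical-rank detection by pivoted QR.

    Returns (full-rank column subset, rank); tolerance 1e-9 times the largest
    column norm. Raises if the design is annihilated (rank 0).
    """
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.size == 0 or not np.any(design):
        raise ValueError("design matrix is zero: weights or basis annihilated the design")
    _, Rq, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rq))
    # diag[0] is the largest column norm after pivoting
    rank = int(np.sum(diag > _RANK_RTOL * diag[0]))
    if rank == 0:
        raise ValueError("design matrix has numerical rank 0")
    keep = np.sort(piv[:rank])
    return design[:, keep], rank


def _nested_ftest(y_w, X_w, D_w, region_id="region", notes=()):
    """Nested-model F-test on whitened data; rank-aware numerator df."""
    n, p0 = X_w.shape
    Qx, _ = np.linalg.qr(X_w)
    r0 = y_w - Qx @ (Qx.T @ y_w)
    rss0 = float(r0 @ r0)
    # project covariates out of the region design (twice, for orthogonality
    # to rounding error — the oracle comparisons run at 1e-10)
    D_res = D_w - Qx @ (Qx.T @ D_w)
    D_res = D_res - Qx @ (Qx.T @ D_res)
    D_kept, q = rank_guard(D_res)
    Qd, _ = np.linalg.qr(D_kept)
    df2 = n - p0 - q
    if df2 <= 0:
        raise ValueError(
            f"region {region_id!r}: design overparametrized (n={n}, p0={p0}, q={q})"
        )
    r1 = r0 - Qd @ (Qd.T @ r0)
    r1 = r1 - Qd @ (Qd.T @ r1)
    rss1 = float(r1 @ r1)
    F = ((rss0 - rss1) / q) / (rss1 / df2)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, q, df2))
    coef, _, _, _ = np.linalg.lstsq(D_kept, r0, rcond=None)
    return F, q, df2, p, coef


def flm_test(
    region: RegionGenotypes,
    data: PhenotypeData,
    fit: NullModelFit,
    genotype_spec: BasisSpec | None,
    effect_spec: BasisSpec,
    weights: WeightSpec | None = None,
) -> AssociationResult:
    """Weighted functional F-test of H0: beta_F = 0 for one region.

    `genotype_spec=None` selects the beta-smooth-only model (genotypes left
    discrete); with identical genotype and effect bases the two paths give
    identical statistics. `weights=None` or shapes (1, 1) give the unweighted
    functional model.
    """
    if region.n != data.n:
        raise ValueError("region and phenotype sample sizes differ")
    if not np.array_equal(region.ids, data.ids):
        raise ValueError("region and phenotype samples are not aligned; align by ID first")
    if region.m < 1:
        raise ValueError("empty region")

    pos = scale_positions(region.positions)
    sm = build_smoother(pos, genotype_spec, effect_spec)
    w = weight_vector(weights, region.mafs)
    D = (region.G * w) @ sm.W

    y_w = decorrelate(fit, data.y)
    X_w = decorrelate(fit, data.X)
    D_w = decorrelate(fit, D)

    F, q, df2, p, coef = _nested_ftest(y_w, X_w, D_w, region.region_id, sm.notes)
    notes = sm.notes
    if q < sm.K_beta:
        notes = notes + (f"rank-deficient design: q={q} < K_beta={sm.K_beta}",)
    return AssociationResult(
        region_id=region.region_id,
        n=region.n,
        m_variants=region.m,
        K_beta_used=sm.K_beta,
        rank_used=q,
        F_stat=F,
        df1=q,
        df2=df2,
        p_value=p,
        beta_F_hat=coef,
        notes=notes,
    )
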