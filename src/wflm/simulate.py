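"""Synthetic data generation and type-I error / power experiments.

The generators emulate exome-like gene regions: per-variant MAFs drawn from a
rare-skewed Beta(0.2, 2) truncated to [1/(2n), 0.5], 30-60 polymorphic
variants per region with at least 10 rare ones (MAF <= 0.03), positions
uniform over a 10 kb span. Population samples draw dosages Binomial(2, MAF)
independently per site; family samples are nuclear families (2 founders + 4
offspring by default) with founder haplotypes drawn per MAF and offspring
genotypes produced by Mendelian gene-dropping, giving the block-diagonal
expected additive relationship matrix R.

Traits are realizations of N(G beta, h2 R + (1 - h2) I) with h2 = 0.29 by
default; beta = 0 gives the null. Effect sizes for causal variants follow
either |beta_j| = log(s) |log10(MAF_j)| / 2 (larger effects for rarer
variants) or |beta_j| = s / sqrt(2 MAF_j (1 - MAF_j)) (equal variance
explained per causal variant).

`run_type1` and `run_power` estimate rejection rates of the weighted
functional F-test over a panel of synthetic regions. For unrelated samples
the null scan is fully vectorized (the test reduces to OLS); for family
samples the null polygenic model is re-fitted by REML for every replicate
in the eigenbasis of R, where the fit is a cheap 1-D search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats

from .basis import BasisSpec, build_smoother, scale_positions
from .flm import RegionGenotypes, _nested_ftest, rank_guard
from .mixedmodel import PhenotypeData, RelationshipMatrix, _fit_rotated, fit_null
from .weights import WeightSpec, weight_vector

__all__ = [
    "SimScenario",
    "EffectVector",
    "FamilyStructure",
    "simulate_population_genotypes",
    "simulate_families",
    "region_panel",
    "draw_effects",
    "simulate_trait",
    "run_type1",
    "run_power",
    "Type1Result",
    "PowerResult",
]

RARE_MAF = 0.03
DEFAULT_H2 = 0.29
REGION_SPAN = 10_000


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# scenario / effect containers


@dataclass(frozen=True)
class SimScenario:
    """One power-simulation scenario.

    prop_causal is the fraction of the causal pool (all variants, or rare
    variants only) that carries an effect; prop_same_direction the fraction
    of causal effects sharing the positive sign; effect_model selects the
    effect-size law ('log_maf' or 'variance_standardized') with scale s.
    """

    prop_causal: float
    prop_same_direction: float = 1.0
    causal_pool: str = "rare_only"
    effect_model: str = "log_maf"
    s: float = 3.0
    h2: float = DEFAULT_H2
    n_replicates: int = 2000
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.prop_causal <= 1):
            raise ValueError("prop_causal must lie in (0, 1]")
        if not (0 <= self.prop_same_direction <= 1):
            raise ValueError("prop_same_direction must lie in [0, 1]")
        if self.causal_pool not in ("rare_only", "all"):
            raise ValueError("causal_pool must be 'rare_only' or 'all'")
        if self.effect_model not in ("log_maf", "variance_standardized"):
            raise ValueError("effect_model must be 'log_maf' or 'variance_standardized'")
        if self.s <= 0:
            raise ValueError("effect scale s must be positive")
        if not (0 <= self.h2 < 1):
            raise ValueError("h2 must lie in [0, 1)")


@dataclass(frozen=True)
class EffectVector:
    """Per-variant effect sizes; zero for non-causal variants."""

    beta: np.ndarray
    causal_idx: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "causal_idx", np.asarray(self.causal_idx, dtype=int))


def effect_magnitude(mafs, model: str, s: float) -> np.ndarray:
    """|beta_j| under the chosen effect law."""
    mafs = np.asarray(mafs, dtype=float)
    if model == "log_maf":
        return np.log(s) * np.abs(np.log10(mafs)) / 2.0
    if model == "variance_standardized":
        return s / np.sqrt(2.0 * mafs * (1.0 - mafs))
    raise ValueError(f"unknown effect model {model!r}")


def draw_effects(region: RegionGenotypes, scenario: SimScenario, seed=None) -> EffectVector:
    """Sample the causal set, signs and magnitudes for one replicate."""
    rng = _rng(seed if seed is not None else scenario.seed)
    mafs = region.mafs
    if scenario.causal_pool == "rare_only":
        pool = np.flatnonzero(mafs <= RARE_MAF)
    else:
        pool = np.arange(mafs.size)
    if pool.size == 0:
        raise ValueError("causal pool is empty under this scenario")
    n_causal = max(1, round(scenario.prop_causal * pool.size))
    causal = rng.choice(pool, size=n_causal, replace=False)
    mags = effect_magnitude(mafs[causal], scenario.effect_model, scenario.s)
    n_pos = round(scenario.prop_same_direction * n_causal)
    signs = np.full(n_causal, -1.0)
    signs[rng.choice(n_causal, size=n_pos, replace=False)] = 1.0
    beta = np.zeros(mafs.size)
    beta[causal] = signs * mags
    return EffectVector(beta=beta, causal_idx=np.sort(causal))


# ---------------------------------------------------------------------------
# genotype generators


def sample_mafs(rng: np.random.Generator, m: int, n: int, sampler=None) -> np.ndarray:
    """Draw per-variant MAFs from a rare-skewed spectrum, truncated to [1/(2n), 0.5]."""
    lo = 1.0 / (2 * n)
    if sampler is not None:
        out = np.asarray([sampler(rng) for _ in range(m)], dtype=float)
        return np.clip(out, lo, 0.5)
    out = np.empty(m)
    filled = 0
    while filled < m:
        draw = rng.beta(0.2, 2.0, size=2 * (m - filled))
        draw = draw[(draw >= lo) & (draw <= 0.5)]
        take = min(draw.size, m - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _positions(rng: np.random.Generator, m: int, span: int = REGION_SPAN) -> np.ndarray:
    return np.sort(rng.choice(span, size=m, replace=False))


def _subset_region(region: RegionGenotypes, idx) -> RegionGenotypes:
    idx = np.sort(np.asarray(idx, dtype=int))
    return RegionGenotypes(
        region.ids, region.positions[idx], region.G[:, idx], region.mafs[idx], region.region_id
    )


def _select_region(ids, positions, G, region_id, m, min_rare):
    """Pick m polymorphic variants (>= min_rare rare) from an oversampled draw.

    The first m polymorphic variants in draw order are kept; if too few are
    rare, trailing common variants are swapped for later rare draws —
    emulating the selection of gene regions with enough rare variants.
    Returns None when the draw cannot satisfy the constraints.
    """
    try:
        full = RegionGenotypes.from_dosages(ids, positions, G, region_id)
    except ValueError:
        return None
    if full.m < m:
        return None
    is_rare = full.mafs <= RARE_MAF
    if int(is_rare.sum()) < min_rare:
        return None
    keep = list(range(m))
    short = min_rare - int(is_rare[:m].sum())
    if short > 0:
        extra = np.flatnonzero(is_rare[m:])[:short] + m
        if extra.size < short:
            return None
        common_kept = [j for j in keep if not is_rare[j]]
        drop = set(common_kept[-short:])
        keep = [j for j in keep if j not in drop] + list(extra)
    return _subset_region(full, keep)


def simulate_population_genotypes(
    n: int,
    m: int,
    maf_sampler=None,
    seed=None,
    *,
    min_rare: int = 0,
    ld_blocks: int | None = None,
    ld_rho: float = 0.5,
    region_id: str = "region",
    max_tries: int = 200,
) -> RegionGenotypes:
    """Simulate an unrelated sample's dosages for one region.

    Sites are independent Binomial(2, MAF) by default; `ld_blocks` switches
    on a latent Gaussian copula with correlation `ld_rho` inside consecutive
    blocks of that size, for LD robustness checks. Regions violating the
    polymorphism or rare-variant constraints are redrawn whole.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    rng = _rng(seed)
    ids = np.array([f"ind{i:05d}" for i in range(n)])
    m_draw = 2 * m + 8  # oversample; monomorphic draws are discarded
    for _ in range(max_tries):
        mafs = sample_mafs(rng, m_draw, n, maf_sampler)
        if ld_blocks:
            G = _copula_dosages(rng, n, mafs, ld_blocks, ld_rho)
        else:
            G = rng.binomial(2, mafs, size=(n, m_draw)).astype(float)
        region = _select_region(ids, _positions(rng, m_draw), G, region_id, m, min_rare)
        if region is not None:
            return region
    raise RuntimeError(f"could not draw a valid region in {max_tries} attempts")


def _copula_dosages(rng, n, mafs, block, rho):
    m = mafs.size
    Z = rng.standard_normal((n, m))
    for start in range(0, m, block):
        stop = min(start + block, m)
        shared = rng.standard_normal(n)
        Z[:, start:stop] = math.sqrt(rho) * shared[:, None] + math.sqrt(1 - rho) * Z[:, start:stop]
    U = stats.norm.cdf(Z)
    return np.stack(
        [stats.binom.ppf(U[:, j], 2, mafs[j]) for j in range(m)], axis=1
    ).astype(float)


@dataclass(frozen=True)
class FamilyStructure:
    """Nuclear-family layout: two unrelated founders plus full-sib offspring."""

    n_offspring: int = 4

    @property
    def size(self) -> int:
        return 2 + self.n_offspring


def nuclear_family_relationship(n_families: int, structure: FamilyStructure) -> RelationshipMatrix:
    """Block-diagonal expected additive relationship matrix (2x kinship)."""
    k = structure.n_offspring
    block = np.eye(structure.size)
    block[2:, 2:] = 0.5 * (np.ones((k, k)) + np.eye(k))
    block[0, 2:] = block[2:, 0] = 0.5  # parent-offspring
    block[1, 2:] = block[2:, 1] = 0.5
    R = scipy.linalg.block_diag(*([block] * n_families))
    ids = np.array(
        [f"fam{f:04d}_{role}" for f in range(n_families) for role in
         ["p1", "p2", *[f"o{j + 1}" for j in range(k)]]]
    )
    return RelationshipMatrix(R=R, ids=ids)


def _gene_drop(rng, n_families, structure, mafs):
    """Founder haplotypes per MAF, offspring by Mendelian transmission."""
    m = mafs.size
    k = structure.n_offspring
    # haplotypes: families x founder x chromosome x variant
    hap = (rng.random((n_families, 2, 2, m)) < mafs).astype(np.int8)
    G = np.empty((n_families, structure.size, m), dtype=np.int8)
    G[:, 0] = hap[:, 0].sum(axis=1)
    G[:, 1] = hap[:, 1].sum(axis=1)
    fam_idx = np.arange(n_families)[:, None]
    var_idx = np.arange(m)[None, :]
    for j in range(k):
        from_p1 = hap[fam_idx, 0, rng.integers(0, 2, size=(n_families, m)), var_idx]
        from_p2 = hap[fam_idx, 1, rng.integers(0, 2, size=(n_families, m)), var_idx]
        G[:, 2 + j] = from_p1 + from_p2
    return G.reshape(n_families * structure.size, m).astype(float)


def simulate_families(
    n_families: int,
    structure: FamilyStructure | None = None,
    maf_sampler=None,
    m: int = 40,
    seed=None,
    *,
    min_rare: int = 0,
    region_id: str = "region",
    max_tries: int = 200,
):
    """Gene-drop one region through nuclear families.

    Returns (RegionGenotypes, RelationshipMatrix); R depends only on the
    pedigree, so callers scanning many regions should reuse it.
    """
    structure = structure or FamilyStructure()
    rng = _rng(seed)
    R = nuclear_family_relationship(n_families, structure)
    n = R.ids.size
    m_draw = 2 * m + 8
    for _ in range(max_tries):
        mafs = sample_mafs(rng, m_draw, n, maf_sampler)
        G = _gene_drop(rng, n_families, structure, mafs)
        region = _select_region(R.ids, _positions(rng, m_draw), G, region_id, m, min_rare)
        if region is not None:
            return region, R
    raise RuntimeError(f"could not draw a valid region in {max_tries} attempts")


def region_panel(
    sample: str,
    n_target: int = 700,
    n_regions: int = 40,
    m_range: tuple[int, int] = (30, 60),
    min_rare: int = 10,
    seed=None,
    structure: FamilyStructure | None = None,
):
    """Panel of synthetic regions sharing one sample.

    Mirrors the experimental setup of scanning pre-selected genes with >= 30
    polymorphic variants and >= 10 rare ones. Returns (regions, R) with
    R = None for the unrelated ('population') sample.
    """
    rng = _rng(seed)
    if sample not in ("population", "family"):
        raise ValueError("sample must be 'population' or 'family'")
    regions = []
    if sample == "population":
        n = n_target
        ids = None
        R = None
        for i in range(n_regions):
            m = int(rng.integers(m_range[0], m_range[1] + 1))
            reg = simulate_population_genotypes(
                n, m, seed=rng, min_rare=min_rare, region_id=f"reg{i:03d}"
            )
            regions.append(reg)
        return regions, None
    structure = structure or FamilyStructure()
    n_families = max(1, round(n_target / structure.size))
    R = None
    for i in range(n_regions):
        m = int(rng.integers(m_range[0], m_range[1] + 1))
        reg, R_i = simulate_families(
            n_families, structure, m=m, seed=rng, min_rare=min_rare, region_id=f"reg{i:03d}"
        )
        R = R or R_i
        regions.append(reg)
    return regions, R


# ---------------------------------------------------------------------------
# trait simulation


def trait_cholesky(h2: float, R: RelationshipMatrix | None, n: int) -> np.ndarray | None:
    """Lower Cholesky factor of h2 R + (1 - h2) I; None encodes the identity."""
    if R is None or h2 == 0:
        return None
    cov = h2 * R.R + (1.0 - h2) * np.eye(n)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("trait covariance is not positive definite") from err


def simulate_trait(
    region: RegionGenotypes,
    beta: EffectVector | np.ndarray | None,
    h2: float,
    R: RelationshipMatrix | None = None,
    seed=None,
    *,
    chol: np.ndarray | None = None,
) -> np.ndarray:
    """Draw y ~ N(G beta, h2 R + (1 - h2) I); beta = None or 0 is the null."""
    if not (0 <= h2 < 1):
        raise ValueError("h2 must lie in [0, 1)")
    rng = _rng(seed)
    n = region.n
    if beta is None:
        mean = np.zeros(n)
    else:
        b = beta.beta if isinstance(beta, EffectVector) else np.asarray(beta, dtype=float)
        mean = region.G @ b
    z = rng.standard_normal(n)
    if chol is None:
        chol = trait_cholesky(h2, R, n)
    if chol is None:
        return mean + z
    return mean + chol @ z


# ---------------------------------------------------------------------------
# experiment drivers


@dataclass
class Type1Result:
    """Null-simulation rejection rates with binomial standard errors."""

    pvalues: np.ndarray
    rates: dict[float, float]
    se: dict[float, float]
    n_replicates: int

    @classmethod
    def from_pvalues(cls, pvalues, alphas):
        pvalues = np.asarray(pvalues)
        n = pvalues.size
        rates = {a: float(np.mean(pvalues <= a)) for a in alphas}
        se = {a: math.sqrt(max(r * (1 - r), a * (1 - a)) / n) for a, r in rates.items()}
        return cls(pvalues, rates, se, n)


@dataclass
class PowerResult:
    """Power estimate at a fixed significance threshold."""

    power: float
    se: float
    threshold: float
    n_replicates: int
    pvalues: np.ndarray


def _region_designs(regions, genotype_spec, effect_spec, weights):
    designs = []
    for reg in regions:
        pos = scale_positions(reg.positions)
        sm = build_smoother(pos, genotype_spec, effect_spec)
        w = weight_vector(weights, reg.mafs)
        designs.append((reg.G * w) @ sm.W)
    return designs


def _population_null_pvalues(regions, designs, n_rep, rng):
    """Vectorized null scan for unrelated samples (the F-test is exact OLS).

    The trait is standard normal and Omega = sigma^2 I, so whitening is a
    scalar and cancels from F; per region the projections are precomputed
    and all replicates assigned to it are scored in one matrix product.
    """
    n = regions[0].n
    ones = np.full((n, 1), 1.0)
    proj = []
    Qx, _ = np.linalg.qr(ones)
    for D in designs:
        D_res = D - Qx @ (Qx.T @ D)
        D_kept, q = rank_guard(D_res)
        Qd, _ = np.linalg.qr(D_kept)
        proj.append((Qx, Qd, q))
    assign = rng.integers(0, len(regions), size=n_rep)
    pvals = np.empty(n_rep)
    for r in range(len(regions)):
        idx = np.flatnonzero(assign == r)
        if idx.size == 0:
            continue
        Qx, Qd, q = proj[r]
        df2 = n - 1 - q
        for start in range(0, idx.size, 4096):
            sl = idx[start : start + 4096]
            Y = rng.standard_normal((n, sl.size))
            R0 = Y - Qx @ (Qx.T @ Y)
            rss0 = np.einsum("ij,ij->j", R0, R0)
            num = np.einsum("ij,ij->j", Qd.T @ R0, Qd.T @ R0)
            rss1 = rss0 - num
            F = (num / q) / (rss1 / df2)
            pvals[sl] = stats.f.sf(F, q, df2)
    return pvals


def _family_scan(regions, R, designs, n_rep, rng, h2, effect_fn=None):
    """Per-replicate scan for family samples, run in the eigenbasis of R.

    Rotating by U from R = U diag(d) U^T makes the trait covariance diagonal,
    so the per-replicate REML fit is a 1-D search over h2 and whitening is a
    row scaling. The simulated trait in the original basis is y = U y_t (for
    the null) or G beta + L z (under the alternative), identical in law to
    what `simulate_trait` draws.
    """
    U, d = R.eigendecomposition()
    n = R.ids.size
    ones_t = U.T @ np.full((n, 1), 1.0)
    designs_t = [U.T @ D for D in designs]
    sd_t = np.sqrt(h2 * d + (1.0 - h2))
    chol = trait_cholesky(h2, R, n) if effect_fn is not None else None
    assign = rng.integers(0, len(regions), size=n_rep)
    pvals = np.empty(n_rep)
    for i in range(n_rep):
        r = assign[i]
        if effect_fn is None:
            y_t = sd_t * rng.standard_normal(n)
        else:
            beta = effect_fn(regions[r], rng)
            y = simulate_trait(regions[r], beta, h2, R, rng, chol=chol)
            y_t = U.T @ y
        h2_hat, _, _, _ = _fit_rotated(y_t, ones_t, d)
        sw = 1.0 / np.sqrt(h2_hat * d + (1.0 - h2_hat))
        F, q, df2, p, _ = _nested_ftest(
            y_t * sw, ones_t * sw[:, None], designs_t[r] * sw[:, None], regions[r].region_id
        )
        pvals[i] = p
    return pvals


def run_type1(
    sample: str = "family",
    basis_spec: BasisSpec = BasisSpec("bspline", 15),
    weights: WeightSpec | None = WeightSpec(1.0, 25.0),
    n_replicates: int = 1000,
    alphas=(0.05, 0.01),
    seed=None,
    *,
    genotype_spec: BasisSpec | None = None,
    n_target: int = 700,
    n_regions: int = 40,
    m_range: tuple[int, int] = (30, 60),
    h2: float = DEFAULT_H2,
    panel=None,
) -> Type1Result:
    """Empirical type-I error of the weighted functional F-test.

    Simulates beta = 0 traits over a panel of synthetic regions, tests each
    replicate against a region drawn at random from the panel, and tabulates
    the proportion of P values at or below each requested alpha.
    """
    rng = _rng(seed)
    if panel is None:
        regions, R = region_panel(sample, n_target, n_regions, m_range, seed=rng)
    else:
        regions, R = panel
    designs = _region_designs(regions, genotype_spec, basis_spec, weights)
    if R is None:
        pvals = _population_null_pvalues(regions, designs, n_replicates, rng)
    else:
        pvals = _family_scan(regions, R, designs, n_replicates, rng, h2)
    return Type1Result.from_pvalues(pvals, alphas)


def run_power(
    scenario: SimScenario,
    sample: str = "family",
    basis_spec: BasisSpec = BasisSpec("bspline", 15),
    weights: WeightSpec | None = WeightSpec(1.0, 25.0),
    seed=None,
    *,
    threshold: float = 1e-3,
    genotype_spec: BasisSpec | None = None,
    n_target: int = 700,
    n_regions: int = 40,
    m_range: tuple[int, int] = (30, 60),
    panel=None,
) -> PowerResult:
    """Power of the weighted functional F-test under one scenario.

    Each replicate draws a region from the panel, samples causal effects per
    the scenario, simulates the trait and tests; power is the proportion of
    P values below `threshold` (10^-3 by default at desk scale; the exome-wide
    2.5e-6 is available by argument).
    """
    rng = _rng(seed if seed is not None else scenario.seed)
    if panel is None:
        regions, R = region_panel(sample, n_target, n_regions, m_range, seed=rng)
    else:
        regions, R = panel
    designs = _region_designs(regions, genotype_spec, basis_spec, weights)

    def effect_fn(region, rep_rng):
        return draw_effects(region, scenario, rep_rng)

    if R is None:
        # unrelated sample: same per-replicate path with the identity R
        pvals = np.empty(scenario.n_replicates)
        assign = rng.integers(0, len(regions), size=scenario.n_replicates)
        ones = np.full((regions[0].n, 1), 1.0)
        for i in range(scenario.n_replicates):
            reg = regions[assign[i]]
            beta = effect_fn(reg, rng)
            y = simulate_trait(reg, beta, 0.0, None, rng)
            _, _, _, pvals[i], _ = _nested_ftest(y, ones, designs[assign[i]], reg.region_id)
    else:
        pvals = _family_scan(
            regions, R, designs, scenario.n_replicates, rng, scenario.h2, effect_fn
        )
    power = float(np.mean(pvals < threshold))
    se = math.sqrt(max(power * (1 - power), 1e-12) / scenario.n_replicates)
    return PowerResult(power, se, threshold, scenario.n_replicates, pvals)
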