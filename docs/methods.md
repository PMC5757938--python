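# Methods

## Model

A region holds `m` biallelic variants at base-pair positions
`t₁ < … < t_m`, affinely rescaled to `[0, 1]`. Exact position ties are
separated by a deterministic jitter of `+k · 10⁻⁶` (scaled units, `k` the
occurrence index within the tie group) and the map renormalized so the
endpoints stay at exactly 0 and 1; functional evaluation needs distinct
arguments, and the jitter keeps results reproducible. A region whose
positions are all identical is rejected.

The trait model is

```
y = X α + G Θ W β_F + h + ε,   h ~ N(0, σ²_g R),   ε ~ N(0, σ²_e I).
```

`G` contains minor-allele dosages: columns are re-polarized so that the
counted allele is the minor one *in the analyzed sample* (MAF = min(p, 1−p)
of half the dosage mean), missing dosages are mean-imputed per variant
before MAF computation (which preserves the allele frequency), and
monomorphic columns are dropped.

### Bases and the smoother matrix

Genotype curves and the effect curve are expanded in one of two bases on
`[0, 1]`:

- **B-splines** — order 4 (cubic) by default, `K − order` equally spaced
  interior knots, boundary knots repeated `order` times. Evaluation is by
  `scipy.interpolate.BSpline.design_matrix`; rows form a partition of unity.
- **Fourier** — odd `K`: the constant plus `(K−1)/2` sine/cosine pairs,
  normalized orthonormal on `[0, 1]` (constant 1, pairs scaled by √2). The
  orthonormal normalization makes the cross-integral analytic; the F-test is
  provably invariant to any invertible re-normalization, and a property test
  asserts that invariance.

The smoother is `W = Φ (ΦᵀΦ)⁻¹ J` with `J = ∫₀¹ φ ψᵀ dt`. `J` is the
(rectangular) identity for Fourier × Fourier; any combination involving
B-splines is integrated by composite 7-point Gauss–Legendre quadrature on
the union of both bases' breakpoints — exact for the piecewise-polynomial
parts, and the Fourier factor is resolved by construction because the
Fourier "breakpoints" subdivide `[0, 1]` into at least `2·k_max + 1`
intervals for maximum frequency `k_max`.

With identical genotype and effect bases, `col(G W) = col(G Ψ)`, so the
full-smoothing model is equivalent to the *beta-smooth only* model (only the
effect curve expanded, `W = Ψ`); both paths are implemented and their
equivalence is asserted to 1e−8 relative across random regions. The
beta-smooth-only path is the default and the one used in all experiments: it
needs no invertible genotype Gram matrix. When the full-smoothing path is
requested and `ΦᵀΦ` is numerically singular (too few variants per knot
span), the code raises and points to the beta-smooth-only path rather than
regularizing silently.

If `K` exceeds `m`, the basis is reduced to the largest valid size ≤ `m`
(odd for Fourier, ≥ order for B-splines) and the reduction is recorded in
the result's notes.

One caveat worth knowing: the Fourier system is periodic, so its rows at
`t = 0` and `t = 1` coincide; a Fourier effect basis can never be saturated
(`K_β = m`) once positions are scaled to span both endpoints. Saturated-basis
checks therefore use B-splines.

### Weights

`Θ = diag(w_j)` with `w_j = Beta(MAF_j; a₁, a₂)`, the beta density, computed
in closed form `MAF^(a₁−1)(1−MAF)^(a₂−1)/B(a₁, a₂)` so that `(1, 1)` yields
*exactly* unit weights and the weighted and unweighted tests are bitwise
identical there. The literature also writes the weight as √w; whether the
density or its square multiplies the genotype column is a real ambiguity
(for a saturated design the F-test is invariant to per-column scaling, but
for smoothed designs it is not), so both conventions are implemented behind
`WeightSpec(convention="density" | "squared_density")` with the density as
default — the convention under which the kernel-test weighting literature
states its `(1, 25)` recommendation. Custom per-variant weights override the
beta rule. Scaling all weights by a common constant leaves the F statistic
unchanged (column-space invariance), which is tested.

A MAF filter (`maf_filter`, default threshold 0.03 when used) is provided as
the comparator to weighting: it removes common variants outright.

### Null model and F-test

Variance components are estimated once per sample under the null (no region
term) by REML — the standard two-step protocol for region scans — and held
fixed for every region's test. With the eigendecomposition `R = U D Uᵀ`
(computed once per sample and cached), the restricted likelihood is profiled
over `h² ∈ [0, 1)` by bounded scalar minimization (tolerance 1e−8); `σ²`
profiles out analytically. If `R` is the identity (max |R − I| < 1e−12) the
components are unidentifiable and the convention `σ²_g = 0`, `h² = 0` is
reported, making the downstream test exactly ordinary least squares. REML
(not ML) is the criterion because it removes fixed-effect bias from the
variance components; the choice matters little for the F-test, which is
scale-invariant.

The region test whitens `y`, `X` and `D = G Θ W` by `Ω^(−1/2)` through the
stored eigendecomposition and compares nested OLS fits:

```
F = [(RSS₀ − RSS₁)/q] / [RSS₁/(n − p₀ − q)],   p₀ = 1 + #covariates,
```

where `q` is the numerical rank (pivoted QR, tolerance 1e−9 × largest
column norm) of the whitened design after projecting out the covariates.
Using the detected rank rather than the nominal `K_β` keeps the test valid
when weighting plus smoothing induce rank deficiency — which happens in
practice for heavily down-weighted common-variant columns — at the cost of a
data-dependent df₁, which is recorded in the result. P values are the upper
tail of `F(q, n − p₀ − q)`. For unrelated samples this is exactly the
classical multiple-regression F-test, verified against an independent
statsmodels nested-OLS oracle to 1e−10.

Covariate projection is applied twice (iterative re-orthogonalization) so
the oracle agreement survives at that tolerance.

## Synthetic data

The generators emulate exome-like gene regions and family samples; they are
the experiment's study conditions, not tuning knobs.

- **MAF spectrum** — Beta(0.2, 2) truncated to `[1/(2n), 0.5]`: rare-skewed,
  with mean ≈ 0.09. Regions carry 30–60 variants; panels require ≥ 10 rare
  variants (MAF ≤ 0.03) per region, mirroring how genes are pre-selected for
  region tests. Candidate variants are oversampled (2m + 8 draws) and the
  first m polymorphic ones kept, swapping in later rare draws when the rare
  count falls short — the in-silico analogue of that gene selection.
- **Positions** — uniform without replacement over a 10 kb span.
- **Population sample** — dosages Binomial(2, MAF), independent across sites
  by default; an optional latent Gaussian copula (correlation 0.5 within
  blocks of 5) adds LD for robustness checks. LD is not part of the default
  conditions.
- **Family sample** — nuclear families of 2 founders + 4 offspring (~700
  individuals ≈ 116 families). Founder haplotypes are drawn per MAF and
  offspring genotypes gene-dropped by Mendelian transmission; `R` is the
  block-diagonal expected additive relationship matrix (parent–offspring and
  sib–sib entries 0.5).
- **Traits** — `y ~ N(Gβ, h²R + (1−h²)I)` with `h² = 0.29` by default;
  `β = 0` is the null. Causal effects follow either
  `|β_j| = log(s)·|log₁₀ MAF_j|/2` (rarer variants get larger effects) or
  `|β_j| = s/√(2·MAF_j(1−MAF_j))` (equal variance explained per causal
  variant; this reading of the variance-standardized law is adopted because
  `Var(G_j) = 2·MAF_j(1−MAF_j)` under Hardy–Weinberg — the alternative
  reading differs only by a constant factor and changes no ordering). Sign
  assignment rounds `prop_same_direction × n_causal` to the nearest integer.

What the generator does **not** emulate: realistic LD by default, population
stratification, genotyping error, non-normal traits, and real exome gene
structure. Passing calibration and power checks therefore demonstrate the
test's statistical construction (whitening, rank handling, weighting), not
robustness to those real-data complications.

## Experiments

- **Type-I error** — traits simulated under `β = 0` over a 40-region panel,
  one region drawn per replicate; the rate is the proportion of P ≤ α. For
  unrelated samples the scan is vectorized (the test is exact OLS and region
  projections are precomputed); for family samples each replicate re-fits
  the null REML model, done cheaply in the eigenbasis of `R` where whitening
  is a row scaling. A dedicated test asserts the eigen-space driver and the
  public `flm_test` produce identical P values on the same trait.
- **Power** — per replicate: draw a region, draw effects per scenario,
  simulate the trait, test. The desk-scale significance threshold defaults
  to 10⁻³: a 2000-replicate run cannot resolve an exome-wide 2.5 × 10⁻⁶
  tail meaningfully, and the weight-setting orderings are
  threshold-robust; the exome-wide threshold remains available by argument.
- **Problem sizes** — n ≈ 700 (both sample types), 40 regions of 30–60
  variants, 10⁴ null replicates (10⁵ for the smallest α on the vectorized
  population path), 2000 power replicates; REML heritability recovery uses
  200 replicates on ~600 relatives. These sizes keep every experiment
  resolvable at its Monte-Carlo error.

All randomness flows from a single integer seed through
`numpy.random.Generator`; every generator and driver is bit-reproducible
from (seed, config).

## Numerical choices and degenerate inputs

- Rank tolerance 1e−9 × largest column norm (pivoted QR).
- REML search tolerance 1e−8 on h², with boundary snapping.
- Relationship matrices must be symmetric to 1e−10 and PSD to −1e−8
  (eigenvalues clipped at zero).
- Degenerate regions (all positions equal, no polymorphic variant, empty
  MAF-filter result), zero-variance traits, rank-deficient covariates and
  overparametrized designs (`n − p₀ − q ≤ 0`) all raise informative errors
  rather than returning numbers.

## Known limitations

- Quantitative traits only; no binary-trait model.
- One polygenic random effect; no multiple variance components or sparse
  kinship optimizations.
- df₁ is the detected rank, so two regions with the same `K_β` can have
  different numerator df; the result notes record when this happens.
- The B-spline full-smoothing path needs enough variants per knot span;
  sparse regions should use the (default) beta-smooth-only path.
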