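# wflm — weighted functional linear models for gene-based association

`wflm` tests whether a genomic region (a gene) is associated with a
quantitative trait by combining all of its variants — common and rare — into
one test, for unrelated cohorts and family samples alike. It is aimed at
statistical geneticists running region-based rare-variant scans on
sequencing or exome data, where single-variant tests are underpowered.

## The model

For a region with `m` variants at physical positions scaled to `[0, 1]`, an
`n × m` minor-allele dosage matrix `G`, covariates `X`, and trait `y`:

```
y = X α + G Θ W β_F + h + ε,      h ~ N(0, σ²_g R),   ε ~ N(0, σ²_e I)
```

- `W = Φ (ΦᵀΦ)⁻¹ ∫₀¹ φ(t) ψᵀ(t) dt` is the `m × K_β` smoother matrix built
  from basis expansions of the genotype curves (`φ`, evaluated as `Φ`) and of
  the effect-size curve `β(t)` (`ψ`). B-spline (default `K = 15`, cubic,
  uniform knots) and Fourier (default `K = 25`, orthonormal) bases are
  supported. With identical bases the model reduces to the *beta-smooth only*
  form `W = Ψ`, which is the default: genotypes stay discrete and only the
  effect curve is smoothed.
- `Θ = diag(w₁ … w_m)` carries per-variant weights
  `w_j = Beta(MAF_j; a₁, a₂)`, the beta density evaluated at each variant's
  minor-allele frequency. `(1, 25)` strongly favours rare variants, the
  arcsine `(0.5, 0.5)` less so, and `(1, 1)` is the unweighted model.
- `R` is the expected additive relationship matrix (2 × kinship; identity for
  unrelated samples). Variance components are estimated by REML, profiled
  over the heritability `h² = σ²_g / (σ²_g + σ²_e)` in the eigenbasis of `R`.

The region effect `H₀: β_F = 0` is tested with the fixed-effects
F-statistic of the mixed model: `y`, `X` and `G Θ W` are whitened by
`Ω^(-1/2)` (with `Ω = σ²_g R + σ²_e I` fixed at the null fit) and compared by
a nested-model F-test whose numerator degrees of freedom are the numerical
rank of the whitened region design.

The package also ships the simulation framework used to characterize the
test: exome-like region generators (rare-skewed MAF spectrum, ≥ 10 rare
variants per region), nuclear-family gene-dropping with the matching
relationship matrix, trait simulation `y ~ N(Gβ, h²R + (1−h²)I)`, and
drivers for type-I error and power experiments.

## Worked example

```python
import numpy as np
from wflm import *

rng = np.random.default_rng(7)
# family sample: 116 nuclear families (2 founders + 4 sibs), one 45-variant gene
region, R = simulate_families(116, m=45, seed=rng, min_rare=10)

# trait: 20% of rare variants causal, effects log(5)|log10 MAF|/2, h2 = 0.29
scen = SimScenario(prop_causal=0.2, prop_same_direction=1.0, causal_pool="rare_only",
                   effect_model="log_maf", s=5.0, h2=0.29)
beta = draw_effects(region, scen, seed=rng)
y = simulate_trait(region, beta, 0.29, R, seed=rng)

data = PhenotypeData(region.ids, y, np.ones((region.n, 1)))
fit = fit_null(data, R)
print(f"REML: h2 = {fit.h2:.3f}")
for label, w in [("unweighted (1,1)", None), ("weighted (1,25)", WeightSpec(1, 25))]:
    res = flm_test(region, data, fit, None, BasisSpec("bspline", 15), w)
    print(f"{label:18s} F = {res.F_stat:7.3f}  df = ({res.df1}, {res.df2})  P = {res.p_value:.3e}")
```

prints

```
REML: h2 = 0.306
unweighted (1,1)   F =   1.234  df = (15, 680)  P = 2.407e-01
weighted (1,25)    F =   2.779  df = (15, 680)  P = 3.389e-04
```

The REML fit recovers the generating heritability (0.29) from the family
structure. The causal signal sits entirely in rare variants, so upweighting
them by `Beta(MAF; 1, 25)` sharpens the same 15-df F-test from an
unremarkable P = 0.24 to P = 3.4 × 10⁻⁴ — the central behaviour of the
weighted model.

The same analysis runs from the shell on VCF or plain dosage-matrix input:

```sh
wflm simulate --preset family --n 700 --m 45 --out-prefix demo --seed 7
wflm test --geno demo.geno.txt --positions demo.pos.txt \
          --pheno demo.pheno.tsv --trait y --kinship demo.kinship.txt \
          --basis bspline --K 15 --weights beta --beta-par 1,25 --out demo.results.tsv
wflm type1 --sample population --replicates 2000 --seed 1
wflm power --sample family --s 5 --replicates 500 --seed 1
```

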