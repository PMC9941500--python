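# gsem-cortex

Multivariate genomic-architecture analysis of many GWAS traits from summary
statistics, built around the workflow used to model the genetic organization
of cortical thickness and surface area across the 34 bilateral
Desikan–Killiany regions: estimate a genetic covariance matrix by
multivariable LD-score regression, discover and confirm latent factor
structure (including bifactor models), test functional-annotation enrichment
of the factor variances, and annotate the resulting cortical parcellation
with spherical spin tests.

It is aimed at statistical geneticists and imaging-genetics researchers who
have per-trait GWAS summary statistics (not individual-level data) and want
a structural-equation view of the shared genetic signal.

## The model

For SNP *j* and traits 1 and 2, LD-score regression rests on the
second-moment expectation

```
E[z1j z2j] = sqrt(N1 N2) * Σ_c τ_c · l(j,c)/M_c  +  ρ N_s / sqrt(N1 N2)  +  a
```

where `l(j,c)` is the LD score of SNP *j* in annotation *c* of size `M_c`,
`τ_c` the per-annotation (co)heritability controlling for annotation
overlap, `ρ` the phenotypic correlation in the `N_s` overlapping
participants, and `a` shared confounding. With a single whole-genome
annotation this is ordinary univariate/bivariate LDSC: the slope gives
heritabilities and co-heritabilities (the matrix **S**), and the intercept
indexes confounding and sample overlap. A multivariate block jackknife
yields the sampling covariance **V** of all unique elements of **S**.

Structural models Σ(θ) = ΛΦΛ′ + Θ are then fit to **S** by diagonally
weighted least squares with weight matrix diag(**V**)⁻¹, sandwich standard
errors using the full **V**, a residual-based model χ², and CFI / SRMR / AIC
fit indices. Bifactor models use unit-variance identification, orthogonal
residual factors, equality constraints on two-indicator factors, and a fixed
zero residual for single-indicator factors. Zero-order stratified
covariances `ζ_t = Σ_c (|M_c ∩ M_t| / |M_c|) τ_c` feed enrichment analysis:
refit with loadings fixed at genome-wide values, free factor variances, and
divide the annotation-specific factor variance by the proportional
annotation size `M_t/M` (null value 1).

Every stage is testable end to end against the packaged synthetic-data
generator, which draws z-statistics with exactly the covariance structure
above from a user-specified factor model and writes a machine-readable
ground-truth record.

## Worked example

```python
import numpy as np
from gsem_cortex.synthetic_data import GenerativeSpec, simulate_sumstats
from gsem_cortex.ldsc_engine import multivariable_ldsc
from gsem_cortex.genomic_sem import build_model, fit, fit_indices

# six traits, two correlated factors (loadings 0.7, r = 0.4), h2 = 0.3
spec = GenerativeSpec.two_factor(k=6, h2=0.3, loading=0.7, factor_r=0.4, seed=3)
study = simulate_sumstats(spec)

pair = multivariable_ldsc(study.sumstats, study.ld, m_ref=spec.M)
print(np.round(np.diag(pair.S), 3))
# [0.303 0.289 0.293 0.307 0.298 0.299]   <- h2 estimates near the true 0.3

assignment = {f"trait{i}": ("F1" if i <= 3 else "F2") for i in range(1, 7)}
res = fit(pair.S, pair.V, build_model(assignment, "correlated"))
fi = fit_indices(res, pair.S, pair.V)
print(round(res.chi2, 2), res.df, round(fi.CFI, 3))
# 6.2 8 1.0    <- the generating model fits; chi2 is within its df
print(round(res.estimates["F1~~F2"], 2))
# 0.36         <- factor correlation near the generative 0.4
```

The printed heritabilities sit within two jackknife standard errors of the
generating value, the model χ² of the true structure is unremarkable
relative to its 8 degrees of freedom, and the factor correlation sits
within sampling error of the generative 0.4.

A command-line entry point `gsem-cortex` exposes the same steps
(`munge`, `ldsc`, `efa`, `cfa`, `spin`, `simulate`) for file-based use;
see `gsem-cortex --help`.

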