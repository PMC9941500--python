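# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
studies do and do not establish.

## Summary-statistics QC (`sumstats_io`)

Munging restricts to a reference SNP list, drops strand-ambiguous (A/T,
C/G) pairs, variants with MAF < 1% or INFO < 0.9 (the INFO filter is
skipped with a logged warning when the column is absent, as is common for
consortium meta-analyses), and aligns every z-statistic to the reference
effect allele, flipping signs for swapped allele pairs. Beta/SE and OR/SE
effects are converted to z before filtering. Filters are applied
sequentially and each removed row is charged to the first filter it fails,
so the removal log always sums to the input row count. Duplicate SNP ids
are resolved by dropping all copies with a warning — with no way to decide
which record is right, keeping any of them risks an inconsistent z/N pair.

Binary traits use the sum of per-cohort effective sample sizes
4·v·(1−v)·N; with effective N the liability conversion uses a sample
prevalence of 0.5, since effective N already absorbs ascertainment. The
observed→liability multiplier is K²(1−K)² / (P(1−P)·φ(Φ⁻¹(1−K))²).

## LD-score regression (`ldsc_engine`)

Univariate: χ²_j regressed on N·l_j/M with a free intercept. Bivariate:
z₁ⱼz₂ⱼ on √(N₁N₂)·l_j/M; the intercept estimates ρ·N_s/√(N₁N₂) plus shared
confounding. Weights combine the 1/max(l_j,1) overcounting correction with
the reciprocal of the model-implied variance of the regressand, whose
parameters come from a step-one fit restricted to χ² < 30 SNPs (two weight
iterations); the step-two regression runs on the full SNP set with those
weights fixed and a free intercept. All intercepts are always free. The
model-implied variance is floored at 0.05 to keep weights finite for
degenerate inputs.

Jackknife: 200 contiguous equal-count blocks in LD-score file order.
Delete-one-block estimates are computed exactly from per-block sufficient
statistics with the full-sample weights held fixed. For k traits all
k(k+1)/2 regressions run on the common SNP intersection with the same
blocks, and V is the joint jackknife covariance of all unique S elements in
column-major lower-triangle (half-vectorization) order, so estimation-error
dependence from sample overlap lands in V's off-diagonals. Negative
heritability estimates are retained in S (standardization to a correlation
matrix refuses them). MHC exclusion is the LD-score producer's
responsibility; the engine does not filter by position.

Self-regression of a trait with itself equals the univariate fit only up
to weighting details (the product regression and the χ² regression build
their weights from slightly different preliminary estimates); agreement is
at the 1–2% level, which the tests reflect.

## Factor structure (`factor_structure`)

Factor counts come from the non-graphical scree rules: Kaiser (eigenvalues
strictly > 1), acceleration factor (position preceding the maximum second
difference of the eigenvalue profile), and optimal coordinates (eigenvalues
above the prediction of a line through the next eigenvalue and the last
one). The EFA is maximum-likelihood extraction (profile likelihood over
uniquenesses, L-BFGS-B on log-uniquenesses with SMC starting values,
uniqueness bounded in [1e-4, 1]; bound hits are reported as Heywood cases)
followed by varimax and promax with power 4 — the conventional default; the
implementation reproduces R's `factanal` + `promax` to three decimals on
population matrices. Note that promax is an approximate oblique rotation:
even on an exact simple-structure population matrix it attenuates factor
correlations (e.g., 0.18 recovered for a generating 0.30) and leaves small
secondary loadings; this is a property of the method, not an estimation
error. Correlation entries outside [−1,1] (possible from LDSC) are clipped
with a warning for eigen/EFA use only; non-positive-definite inputs are
eigenvalue-clipped at 1e-8. Sign convention: each factor's
largest-magnitude loading is positive. Assignment: an indicator joins the
factor where its loading exceeds 0.5, else the factor with the largest
loading; indicators exceeding the threshold on two or more factors are
flagged as cross-loading and the cross-loading is not carried into
confirmatory models. Ties break toward the lower factor index and are
logged.

## Confirmatory models (`genomic_sem`)

Estimation is diagonally weighted least squares: θ̂ minimizes
(s − σ(θ))′ diag(V)⁻¹ (s − σ(θ)). Standard errors use the sandwich
(J′WJ)⁻¹J′WVWJ(J′WJ)⁻¹ with the full V; the model χ² is Browne's
residual-based statistic with weight V⁺ projected off the model tangent
space, which is exactly zero at a perfect fit and asymptotically χ²_df
otherwise. Optimization is L-BFGS-B with the analytic Jacobian of σ(θ),
gradient tolerance 1e-8, at most 5000 iterations, and a fixed deterministic
start (loadings 0.5, residual variances 0.5·diag(S), covariances 0).
Non-convergence is a reported outcome (`converged=False`), never an
exception — constrained comparison models that fail to converge are
substantive results. If V has negative eigenvalues it is clipped at 1e-10
with the maximum pre/post discrepancy logged.

Identification rules are enforced automatically when building specs:
unit-variance factors, equality-constrained loadings for two-indicator
factors, zero residual variance for single-indicator factors, and fully
orthogonal factors in the bifactor (general + residual) layout.
Standardized estimates divide by √diag(S) of the observed matrix. CFI is
clamped to [0,1] with a small-denominator guard for the case where even the
independence model fits; SRMR averages squared correlation-metric residuals
over all unique elements including the diagonal; AIC = χ² + 2q.

The residual-covariance search frees, one at a time, the indicator pair
with the largest absolute standardized residual of S − Σ(θ̂), keeps it when
the freed parameter's Wald p < α (default 0.01), and stops otherwise;
non-converging refits blacklist the candidate and the search moves to the
next-largest residual. Because the tested candidate is selected as the
maximum over many correlated residuals, the family-wise probability of one
spurious inclusion under a correct model is larger than the per-test α —
about 7% under the reference simulation conditions below — which is a
property of any forward residual search at a fixed per-test threshold.

Joint models with external traits combine two measurement models over a
block-structured S with all brain-factor × external-factor correlations
free, extend the residual search to brain-indicator × external-indicator
pairs, and flag correlations against a configurable Bonferroni family
(default: #brain indicators × #external indicators). The omnibus equality
test compares free vs equality-constrained cross-correlations by χ²
difference.

## Stratified enrichment (`stratified_enrichment`)

The stratified regression fits all annotation columns √(N₁N₂)·l(j,c)/M_c
jointly per trait pair with a free intercept, genome-wide-model weights,
and the same multivariate jackknife (replicates are stored per annotation
so linear functionals propagate exactly). Rank-deficient designs raise an
error naming the collinear annotations. Zero-order conversion applies
ζ_t = Σ_c (|M_c∩M_t|/|M_c|)·τ_c element-wise, on the point estimates and on
every jackknife replicate — no delta-method approximation. Screening
eigen-clips each ζ_t to the nearest PSD matrix (clipping at zero; no
Frobenius-optimal alternating projections — the screen only needs the
magnitude of the repair) and excludes an annotation when any element moves
by more than 1.96 of its jackknife SE; the screen applies to the S-side
elements with V-derived SEs.

Enrichment fixes the loadings at the genome-wide estimates, frees factor
and residual variances, refits on (ζ_t, V_t), and divides the factor
variance and its SE by M_t/M. The genome-wide factor variance is 1 by
identification, so the whole-genome annotation's enrichment is 1 by
definition and is reported as exactly 1. The default one-tailed p tests
departure above the null enrichment of 1, i.e., the upper tail of
(enrichment − 1)/SE; the ratio enrichment/SE is also reported as an
alternative column since both conventions appear in practice.
Continuous/flanking/control annotations can be included in the regression
and excluded from enrichment reporting via the `report_annotations`
argument.

## Topographical annotation (`topo_annotation`)

Spins act on region centroids on the unit sphere (the analysis operates on
34 bilateral regions, so centroid granularity is the natural choice; a
synthetic stand-in centroid table with the standard Desikan–Killiany names
ships with the package and is user-replaceable by CSV). Each spin draws a
uniform rotation (QR of a Gaussian matrix, sign-corrected), applies it to
left-hemisphere centroids and its x-mirrored counterpart to the right
hemisphere, and relabels every region by the nearest original centroid
within its hemisphere; repeated labels are allowed. Bilateral-average maps
are represented on left-hemisphere centroids only, where the mirrored
counterpart is redundant by construction. Equidistant ties break toward
the lower region index and are logged.

Categorical map pairs use the Fisher exact dependence p as the test
statistic: exact for 2×2, otherwise Monte-Carlo Freeman–Halton with fixed
margins (shared permutation draws across all spins of one comparison; the
log-factorial cell-count statistic is computed through one one-hot matrix
product per chunk). p_spin is plus-one corrected, so its floor is
1/(n_spins+1). Monte-Carlo Fisher p values are discrete; exact ties are
resolved by the table's Cramér's V (a tied spin counts as at-least-as-
extreme only when its dependence is at least as strong), which preserves
exchangeability under the null and lets a maximally dependent observed map
reach the permutation floor. Continuous maps use a one-way omnibus F across
factor groups with Benjamini–Hochberg adjustment across the map collection;
constant maps and single-group labelings are flagged with p_spin = 1.

Calibration caveat: centroid-level spins are only approximately exact —
spun maps are surjections (labels can repeat) while the observed map is
not, so the permutation distribution is not perfectly exchangeable with
the observed statistic. Under fully independent random maps the measured
rejection rate at α = 0.05 is near 7% rather than 5%, varying with the
particular spin draw (batches between 6% and 10% were observed). A control
run that replaces the spins with exact uniform permutations — an
exchangeable null by construction — is calibrated (~5–6%), which isolates
the inflation to the spin ensemble itself rather than the test machinery.
Conclusions that hinge on p_spin values within a factor of ~1.5–2 of a
threshold deserve caution.

## Synthetic data (`synthetic_data`)

Generation happens at the z-statistic level: per SNP the trait vector is
multivariate normal with exactly the stratified-LDSC covariance — built as
a sum of independent Gaussian components, one for the intercept matrix
(identity + overlap + confounding) and one per annotation — so generator
and estimator are inverses in expectation. Individual-level genotypes
would add cost without adding testable surface; per-SNP independence is the
standard LDSC design approximation, with LD entering only through the
scores. LD scores have block-level gamma means (100 contiguous blocks,
shape 6, scale 8, per-SNP gamma(2, 0.5) skew on top of a baseline of 1),
supporting the jackknife; stratified scores equal the genome-wide score
inside a SNP's own annotation of the disjoint partition and 0 elsewhere,
so they sum to the genome-wide score. τ matrices derive from standardized
loadings, factor correlations, per-trait h², per-pair overlap (ρ, N_s) and
confounding, and per-annotation variance shares (τ_c = share_c · S); an
optional residual correlation can be planted between trait pairs. Seeds
are mandatory; every study carries a serialized truth record.

The reference study conditions used throughout the tests and the
acceptance script are k = 6 traits on two factors (standardized loadings
0.7, factor correlation 0.4), h² = 0.3, M = 20,000 SNPs, N = 20,000 per
trait, 200 jackknife blocks — small enough for minutes-scale runs on one
CPU while leaving LDSC sampling error visibly non-trivial. What passing
these tests shows: the estimators are unbiased and their jackknife/sandwich
uncertainties are calibrated *under the model's own assumptions*. What they
do not show: robustness to real-data features the generator omits —
realistic LD (scores here are exchangeable draws, not panel-derived),
MAF-dependent architecture, uneven per-SNP sample sizes, assortative
mating or ascertainment effects on the intercept, and annotation structure
correlated with LD.

## Numerical conventions

Half-vectorization is column-major lower triangle everywhere. Nearest-PSD
repairs are eigenvalue clips (floor 0 for ζ screening, 1e-10 for V, 1e-8
for EFA correlation inputs). The DWLS weight floor is 1e-30 on diag(V).
Optimizer tolerances are stated above; all randomness flows through
explicit `numpy.random.Generator` seeds.
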