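# Methods

`reactnorm` asks whether the genetic and residual variance of a quantitative
trait change along a continuous environmental gradient — in the motivating
setting, a temperature–humidity index (THI) summarizing heat load on beef
cattle — and whether apparent interaction signals survive once the
correlation between the trait and the gradient itself is modeled.

## Model family

Each animal carries one phenotype record `y_i` and one covariate value
`c_i` (its standardized THI).  Genetic and residual effects are zero- and
first-order random regressions on `c`:

    y_i = mu + alpha0_i + alpha1_i c_i + tau0_i + tau1_i c_i

with coefficient covariances `K_g = cov(alpha0, alpha1)` (2×2) and
`K_e = cov(tau0, tau1)`.  Genetic coefficients are correlated across animals
through the genomic relationship matrix `A` (entrywise, a Hadamard
structure): `cov(y_i, y_j)` carries `A_ij · phi_i K_g phi_j'` with
`phi_i = (1, c_i)`.  Residual coefficients are independent across animals,
so their contribution `phi_i K_e phi_i'` is purely diagonal — each animal
has a single record, hence no off-diagonal residual covariance exists to
estimate.

The multivariate form adds the adjusted covariate `c* = mu_2 + beta + eps`
as a second trait, where `beta` (GRM-structured) and `eps` are the
covariate's own genetic and residual components.  Cross-covariances
`cov((alpha0, alpha1), beta)` and `cov((tau0, tau1), eps)` complete 3×3
joint genetic and residual covariance blocks.  These channels absorb
genotype–environment (G–E) and residual–environment (R–E) correlation;
without them, such correlation can masquerade as interaction variance.

Eight models arise by switching components on and off — univariate GREML,
three univariate reaction-norm models (G×E, R×E, both), bivariate GREML,
and three multivariate reaction-norm models — with free-parameter counts
2/4/4/6 and 6/9/9/12.  Six likelihood-ratio comparisons (M1–M6) test the
combined and orthogonal interaction hypotheses within each family; the
degrees of freedom are (4, 2, 2, 6, 3, 3).  P-values use the plain
chi-square reference with df equal to the free-parameter difference; no
boundary mixture correction is applied, which makes the interaction tests
conservative at the null (a variance constrained to be non-negative
contributes roughly half a chi-square).  The collinearity magnitude
`M(G×E & R×E) − M(G×E|R×E) − M(R×E|G×E)`, with `M` twice the log-likelihood
gain, measures how much interaction evidence the two channels share; `M` is
defined on the 2·logL scale so each magnitude coincides with the
corresponding LRT statistic.

## Estimation

The restricted likelihood is maximized over the free covariance blocks.
The primary optimizer is average-information (AI) REML on the
variance-component scale — the standard fast algorithm for GREML-type
models — with three safeguards:

- **Feasibility**: candidate steps are capped at the largest multiple
  keeping every block positive semi-definite (bisection on 3×3 Cholesky
  checks), rather than projecting after the fact.
- **Active set**: a variance that reaches zero with a non-positive gradient
  is frozen together with its covariances, and the Newton system is solved
  in the reduced space; frozen components are released the moment their
  gradient turns positive.  This makes boundary fits (the common case under
  null data) converge as fast as interior ones.
- **Verification polish**: a short quasi-Newton pass on the log-Cholesky
  scale follows convergence; if it finds a better point (a boundary-adjacent
  local dip), polishing continues to full convergence, and randomized
  restarts back it up.

Gradients are analytic: every `tr(P dV)` term reduces to a quadratic form
in the component loading vectors after one matrix inversion per iteration,
so a gradient costs one Cholesky factorization plus O(n²).  The restricted
likelihood includes its full constant, making the value equal to the
log-density of an orthonormal error-contrast basis — the property the test
suite exploits by comparing against an independently assembled dense
multivariate-normal oracle at small n.

Standard errors come from the inverse observed information (central
finite differences of the analytic gradient over the vech parameters);
average-variance summaries and heritabilities get delta-method errors.
BLUPs of the regression coefficients are the usual conditional means, and
breeding values are `g_i = alpha0_i + alpha1_i c_i`.

Within the comparison ladder, models are fitted small-to-large with warm
starts (the two single-interaction fits merge into the full model's start),
and any alternative that lands below its null is refitted from the null's
estimates embedded exactly, which restores the nesting inequality up to
optimizer tolerance.  REML is the default criterion; ML is available and a
comparison always uses one criterion throughout.

Multi-trait GREML (up to four traits, unstructured covariances) is
implemented separately through the spectral decomposition of the GRM, which
turns each likelihood evaluation into n independent t×t problems.  Missing
phenotypes are handled listwise.

## Data preparation

- **THI**: `THI = (1.8 T + 32) − (0.55 − 0.0055 H)(1.8 T − 26.8)` from
  daily maximum temperature and mean relative humidity, averaged over a
  configurable pre-slaughter window (default 45 to 15 days before
  slaughter, both endpoints inclusive — the interval most relevant to
  carcass quality).  A whole-growth-period variant averages from birth to
  slaughter, by default through calendar-month means.  Standardization to
  zero mean and unit variance uses the population (divide-by-n) convention,
  computed on the post-filter analysis set.
- **Genotype QC**: animals with more than 10% missing calls are removed
  first; then SNPs with MAF < 0.01, missingness > 10%, or a 1-df
  Hardy–Weinberg chi-square p < 1e-4, each filter in a single pass.  The
  missingness reading of the "call rate" filter is the conventional one;
  thresholds are recorded in the QC report.  Sex-chromosome SNPs can be
  excluded via an annotation list.
- **GRM**: `A = W W' / m` with `W` column-standardized after SNP-mean
  imputation, population-sd convention, so `mean(diag(A)) = 1` exactly —
  a sharp internal check.  Principal components are eigenvectors scaled by
  the square root of their eigenvalues, largest-magnitude loading positive.
- **Pre-adjustment**: per-trait outlier removal at ±3 sample standard
  deviations, then removal of contemporary-group/location levels with
  fewer than 5 records (a strict "more than 5" reading is available).
  Fixed-effect selection runs ordinary least squares over the 2×4 grid
  {with/without 10 GRM PCs} × {no THI, linear, quadratic, linear+quadratic},
  ranked by AIC = 2k − 2 logL (k counts coefficients plus the residual
  variance), ties toward fewer parameters.  Residuals are then transformed
  by the rank-based inverse normal (RINT), rank r mapping to the standard
  normal quantile of (r − 0.5)/n; Blom's offset is available but differs
  only in the third decimal.  The covariate's second-trait form is its
  residual on the non-THI fixed effects, centered.  Adjustment is
  two-stage (residualize, then mixed models on residuals) rather than
  joint estimation inside REML, mirroring the analysis design this package
  reproduces; outlier filtering acts on raw phenotypes before adjustment.

## Synthetic data

The generator draws genotypes from a Balding–Nichols island model
(ancestral frequencies uniform on the configured MAF range; optional
F_ST-parameterized subpopulations), builds the GRM, then draws
`(alpha0, alpha1, beta)` from N(0, G3 ⊗ A) via factorizations of `A`
(jittered by 1e-8 on the diagonal when rank-deficient, as whenever m < n)
and `(tau0, tau1, eps)` from N(0, E3 ⊗ I).  Sampling the effects directly
from the multivariate normal — rather than summing per-SNP effects — makes
small-sample covariances exact draws from the target, which keeps
parameter-recovery tests sharp.  The raw covariate is
`location_effect[subpop] + beta + eps`; its z-score enters the polynomial
basis, and `beta + eps` (the location-adjusted value) is the second-trait
phenotype.  Phenotypes reconstruct exactly from the stored truth
components.

Named scenarios fix the study conditions: trait-side variances total 1.0
in the additive case (h² = 0.4, a typical carcass-trait value), slope
variances are 30% of the corresponding intercept variance when switched
on, and the covariate splits its unit variance equally between `beta` and
`eps`.  The `combined` scenario uses
K_g = [[0.4, 0.1], [0.1, 0.2]], K_e = [[0.5, −0.05], [−0.05, 0.15]],
cross-covariances (0.1, 0.05) and (−0.05, 0.03).  The `corr_only`
scenario induces a G–E correlation of 0.3 through cov(alpha0, beta) with
no interaction variance at all — the confounding configuration in which
unmodeled correlation can generate spurious interaction signals; the
correlation is induced directly rather than through stratification, which
isolates the mechanism (stratified populations are available as a harder
variant via `n_subpops`/`fst`/`location_effects`).

What the generator does **not** emulate: linkage disequilibrium, pedigree
structure, selection, repeated records, seasonal weather autocorrelation,
or any calibration to the real distribution of THI and breeding values
across farms (that joint distribution is not publicly documented).
Passing tests therefore demonstrate correctness of the machinery and the
qualitative phenomena under the model's own assumptions, not quantitative
agreement with any particular cattle population.

## Numerical choices and conventions

- Convergence: relative log-likelihood change below 1e-8 (Newton decrement
  for the AI stage) with a gradient check; L-BFGS-B polish uses matching
  tolerances.  LRT statistics are clipped to zero when within −1e-6.
- Population-sd (divide-by-n) standardization everywhere (covariate,
  genotypes), for internal consistency and the exact mean-diagonal check.
- Degenerate inputs raise typed errors: zero-variance covariate,
  empty QC panel, zero-variance genotype columns after QC, non-PSD joint
  covariances (reporting the offending eigenvalue).
- The second-trait phenotype is centered and receives its own grand mean;
  the REML fixed-effect design is one intercept per modeled trait.
- The residual-variance contrast between two models is a Wald z-test on
  the average residual variances with delta-method errors; it assumes the
  two fits are independent, which is false on shared data, and is labeled
  an approximation in its output.

## Study sizes used by the reproduction script

Simulation studies are sized to run comfortably on a single CPU:
parameter recovery uses 10 replicates at n = 500 with 2,000 SNPs;
type-I-error calibration uses 200 replicates at n = 150; the
spurious-signal contrast uses 100 replicates at n = 300; bias-direction
and invariance checks use 30 replicates at n = 300.  The same drivers
accept larger sizes for anyone wanting tighter Monte-Carlo error.

## Calibration behavior of the ladder tests

The interaction hypotheses pin variances to zero, which places the null on
the boundary of the PSD cone: a slope variance of zero forces every
covariance involving that slope to zero as well.  Two consequences, both
measured by the reproduction script:

- The plain chi-square reference is markedly conservative.  In the null
  scenario the M2/M5 rejection rates at nominal 5% come out near 1%, and
  the p-values are visibly super-uniform.  This is the safe direction for
  inference (reported interactions are, if anything, understated), and it
  matches the common practice the ladder reproduces.
- The usual equal-weight mixture of chi-square(df−1) and chi-square(df)
  (available via ``lrt(..., boundary_correction=True)``) is *still* too
  liberal-side-of-correct here, because the cone couples the new
  covariances to the new variance: the effective number of free directions
  at the null is below df−1.  Exact calibration would require a
  case-specific cone projection or a parametric bootstrap, both outside
  this package's scope; the flag is provided for sensitivity analysis.

Relatedly, the spurious-interaction confounding channel — a genetic
correlation between trait and covariate with no interaction variance —
produces only a weak distortion under the `corr_only` preset: conditioning
on the covariate induces a mean shift of roughly
`rho · sigma_alpha0 · (genetic share of c) · (GRM shrinkage)` per unit of
`c`, about 0.07 here, whose square (~0.005 in variance units) sits an
order of magnitude below the slope-variance detection threshold at the
preset's cohort sizes.  Spurious-signal inflation of the univariate ladder
should therefore be expected under *stronger* confounding — most
plausibly population stratification aligned with the environmental
gradient (available through `n_subpops`, `fst` and `location_effects`) —
rather than under the isolated moderate-correlation mechanism the preset
deliberately isolates.  The reproduction script reports the measured rates
for both ladders under the preset as-is.

## Known limitations

- Only first-order (linear) reaction norms; higher polynomial orders are
  out of scope.
- One record per animal; no environmental relationship matrix for the
  residual side.
- Boundary LRT calibration as described above: plain reference
  conservative, standard mixture not exact for this cone geometry.
- Fixed-effect pre-adjustment ignores the uncertainty it removes; the
  variance-component stage treats adjusted phenotypes as data.
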