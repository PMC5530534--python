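# Methods

`bandreg` implements a two-stage Bayesian analysis for predicting grain
yield of wheat lines from multi-environment field trials in which every
plot also carries a hyperspectral reflectance curve. This note records
the statistical model, the numerical choices behind it, what the
synthetic generator does and does not emulate, and the known
limitations.

## The two-stage model

**Stage one (per environment).** Plots follow a resolvable
incomplete-block (alpha-lattice) layout: trials, replicates within
trials, and incomplete blocks within replicates. For each environment
*i* and each trait (yield and every reflectance band at every
time-point) the plot model is

    y = μ_(genotype) + t_(trial) + r_(rep within trial)
        + b_(block within trial, rep) + ε,

with genotype-in-environment means μ_ij fixed and design terms random,
all variances environment-specific. Variance components are estimated
by REML, the means by generalized least squares (BLUEs), and each BLUE
carries an inverse-variance weight ω_ij — the corresponding diagonal
element of (X'Σ⁻¹X)⁻¹ inverted — so that downstream models can account
for heterogeneous precision. Check genotypes take part in this stage
but are dropped from the second-stage table.

**Stage two (the model catalog).** The second stage regresses the yield
BLUE of each (environment, genotype) cell on combinations of:

* fixed environment effects (cell-means coding, no global intercept);
* a line effect with covariance σ²K for a kernel K — the genomic
  relationship matrix G = WW′/m from column-centered marker dosages
  (mode WG), the pedigree additive relationship matrix A (mode WA), or
  the identity (mode WO);
* a genotype-by-environment effect with Kronecker covariance
  (K ⊗ I)σ²;
* reflectance terms, either the p raw band covariates (conventional
  models) or the S-dimensional functional-basis scores of the band
  curves (functional models), each optionally doubled with
  environment-specific copies (band-by-environment interaction).

The fourteen model structures M1–M14 enumerate these combinations; see
`bandreg.model_catalog` for the table.

## Functional representation

A cell's 250-band reflectance vector is treated as a discretized smooth
curve x(k) on [392, 851] nm. It is projected by least squares onto a
truncated basis (cubic B-splines with equally spaced knots, or an
orthonormal Fourier basis; 21 functions by default), and the regression
term ∫x(k)β(k)dk becomes x′d with scores x = J′ĉ, where J_ls = ∫φ_l ψ_s
is computed by composite Simpson quadrature on a fixed 4096-point grid.
This reduces 250 correlated regressors to 21 per term.

Smoothness of β(k) is imposed through the prior N(0, σ² P⁻¹) with the
second-derivative penalty P_ij = ∫ψ″_i ψ″_j. The design is
post-multiplied by the symmetric square root of P⁻¹ so the sampler sees
i.i.d. coefficients. Two details matter:

* **Penalty null space.** For cubic B-splines P is singular on the
  constant and linear functions (their second derivative vanishes). A
  pseudo-inverse square root would *delete* these directions from the
  model — an infinite penalty exactly where the smoothing prior intends
  none. We instead floor eigenvalues at 1e-5 of the largest before
  inversion, the smoothing-spline convention of leaving the polynomial
  null space in the model essentially unpenalized. For the Fourier
  basis the (1,1) entry of P is set to 1 so the constant's prior is not
  degenerate at zero. An identically-zero penalty (piecewise-linear
  splines) falls back to identity whitening with a warning. The
  penalty can also be disabled entirely (`use_penalty=False`), in which
  case the prior is isotropic on the basis coefficients.
* **Identifiability of the common/interaction split.** The common
  coefficient β₁(k) and the environment-specific β₂i(k) are only
  identified up to a shift between them (adding c(k) to every β₂i and
  subtracting it from β₁ changes nothing). Reported curves use the
  sum-to-zero-over-environments convention: the environment mean of
  the β₂i estimates is folded into β₁.

## Priors and the Gibbs sampler

Fixed effects get N(0, 10000) priors. Every random block shares one
variance with a scaled inverse chi-square prior in the convention
σ² = S/χ²_df (mode S/(df+2)); the conjugate update is
(S + SS)/χ²_{df+k}. Unless overridden, hyperparameters follow the
explained-variance partition rule of Bayesian whole-genome regression
software: df = 5, and the scale is set so the prior mode corresponds to
an equal share of half the response variance remaining after the fixed
effects, normalized by the block's mean column sum of squares. The
naive alternative — splitting the raw response variance across blocks —
fails badly here: the weighted response variance is dominated by
environment-mean differences and the weight scaling, so block variances
never shrink.

The residual variance prior uses scale = df = 2×10¹⁰, which pins σ²_e
at 1 with negligible variability. This is deliberate: rows are
pre-scaled by √ω_ij at fit time, so a unit residual variance realizes
var(γ_ij) = 1/ω_ij, propagating first-stage precision into the second
stage.

Kernel blocks are compiled in the eigenbasis of their kernel
(Z V Λ^{1/2} with i.i.d. coefficients), which makes every block a
ridge block; for complete tables these columns are orthogonal, so
single-site Gibbs mixes well there. Blocks of ≤128 columns (environment
effects, functional scores and their environment copies) are instead
drawn jointly from their multivariate-normal full conditional: the
common and environment-specific functional blocks overlap, and
single-site sweeps move between them arbitrarily slowly. Raw-band
blocks (up to 250 + 3×250 columns) stay single-site, as in standard
whole-genome regression samplers. Defaults are 30,000 iterations with
20,000 burn-in and no thinning; seeded runs are bit-reproducible (the
core is a compiled numba kernel with an explicit seed).

## Cross-validation

Two schemes over (environment, genotype) cells, with the identical
partitions reused across models so comparisons are paired:

* **50CV** — per environment, half the lines (floor) go to training,
  drawn independently per environment; a line that would be unobserved
  everywhere is swapped into training in one uniformly chosen
  environment. Bands of test cells remain observed (they are measured
  on the plots); only yield is predicted.
* **90CV** — one focal environment keeps floor(0.10·n) lines in
  training, the rest of its cells are predicted; other environments are
  complete.

Accuracy is the per-environment Pearson correlation between predicted
and observed second-stage yield values over test cells (reported as the
mean APC and standard error sd/√n over partitions; correlations are
computed against the second-stage BLUEs, the response the models
actually see). Fewer than 3 test cells in an environment yields a
missing value.

## The synthetic generator

`bandreg.synthetic_data` creates complete experiments with exported
ground truth. Defaults define the desk-scale study conditions: 300
lines, 3 environments, 10 trials × 3 replicates × 6 blocks of 5 with 2
checks per trial, 100 bands on [392, 851] nm, one time-point. The
published-scale configuration (976 genotyped lines inside a 39-trial /
1170-entry layout, 250 bands, 9 time-points) is provided for
structural checks.

Yield variance components (t/ha²): line 0.30, G×E 0.10, trial 0.05,
replicate 0.03, block 0.02, plot error 0.10, on environment means
(6, 5, 4). The functional band signal is parameterized by the variance
its contribution adds across lines — 1.0 for the common term and 0.5
for the band-by-environment term — rather than by raw coefficient
amplitude, because a coefficient amplitude says nothing about signal
strength until it meets the realized curve variation. These values make
reflectance the dominant yield predictor, consistent with the empirical
finding that whole-spectrum models outperform genomic-only models in
this setting; they are also the regime in which the model-ranking and
coefficient-recovery properties of the method can be demonstrated at
desk scale.

Reflectance curves are a vegetation-like mean profile (green bump plus
red-edge sigmoid) plus smooth basis-coefficient deviations from three
sources: a kinship-correlated heritable line component (sd 0.05), an
independent non-genetic line component (sd 0.03), and a
line-by-environment component (sd 0.05), plus a common environment
shift and per-band plot noise (sd 0.005). The mixture matters: if the
line-level curve variation were entirely kinship-correlated, the common
functional contribution would lie exactly in the span favored by the
kernel line effect and β₁ would be structurally confounded with g.

Pedigrees are random-mating over 2 generations from 40 founders, with
markers gene-dropped allele by allele; a percent of markers are made
mostly-missing or rare so the QC filters are exercised.

**What passing tests do and do not show.** The generator's curves are
genuinely low-dimensional (a 15-function spline span), its noise is
Gaussian and homoscedastic, trials have no spatial trends, and band
noise is independent across wavelengths. Real spectra have sharper
local features, wavelength-correlated noise, and atmospheric/sensor
artifacts; real trials have spatial gradients that alpha-lattice blocks
only partially capture. Recovery and ranking results here demonstrate
the machinery is correct and well-calibrated under the stated
conditions — not that equal accuracy would be achieved on any real
trial.

**A caution on "bands carry no signal" nulls.** Even with all
functional coefficients at zero, band models outperform no-band
baselines whenever line-stable curve variation exists: the observed
spectrum acts as a phenomic fingerprint of line identity, and a model
that regresses yield on it transfers line effects to cells where the
line is unobserved. This is a real prediction channel, not leakage.
The zero-signal tests therefore remove line-stable curve components,
keeping only the non-transferable line-by-environment variation.

## Numerical choices

* REML maximizes the profile log-likelihood by L-BFGS-B on log
  variances with the exact analytic gradient; likelihood and gradient
  are evaluated through Henderson's mixed-model equations after
  absorbing the (diagonal) genotype block, so each evaluation costs one
  Cholesky of the random-effect block. Convergence: gradient tolerance
  1e-8, 200 iterations; components finishing on the floor (1e-8 of the
  trait variance) are reported as 0. The dense-matrix likelihood and an
  external mixed-model fit serve as test oracles.
* GLS BLUEs and weights use the Woodbury identity on the random-effect
  block; zero variance components simply drop their columns.
* Quadrature: composite Simpson on 4096 points per integral (error
  far below the 1e-6 oracle tolerance for these smooth integrands).
* Kinship PD repair adds ε·I starting at 1e-8·trace/n, escalating
  tenfold until Cholesky succeeds, capped at 1e-2 relative.
* Marker QC order is fixed: missingness filter (> 30% dropped), mean
  imputation, then MAF filter (strictly < 0.05 removed, computed from
  imputed dosages).

## Limitations

* The second stage carries only the diagonal of Ψ⁻¹ (standard
  weighted two-stage practice); full covariance propagation is out of
  scope.
* Band BLUEs enter as unweighted covariates; their own first-stage
  uncertainty is ignored.
* No spatial (row-column) adjustment, no multi-trait stage one, no
  free-knot or adaptive bases, no model averaging.
* The sampler provides variance chains and posterior summaries but no
  formal convergence diagnostics beyond what the tests check.
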