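# Methods

## Model and estimation

One trait at a time, plot values from a randomized complete block MET
are modelled as

    Y_ijk = mu + a_i + t_j + (at)_ij + y_jk + e_ijk,

with genotype `a_i ~ N(0, s2_g)`, environment `t_j ~ N(0, s2_e)`,
interaction `(at)_ij ~ N(0, s2_gxe)` and plot error
`e_ijk ~ N(0, s2_eps)` independent, and block-within-environment `y_jk`
fixed. Every environment is one year x location combination and is an
opaque label; blocks are nested within environments.

**Block coding.** A model with random environments and *fixed* blocks
nested in them is only coherent if the fixed space excludes the
environment means: with one dummy per block, every environment
indicator is a sum of its block dummies, all REML error contrasts are
then orthogonal to the environment design and `s2_e` drops out of the
restricted likelihood entirely. We therefore code blocks as sum-to-zero
contrasts *within* each environment plus a global intercept. Block
offsets shift plots within an environment; differences between
environment means belong to the random environment term. The engine
reproduces an independent REML implementation (lme4 with the identical
contrast coding) to six significant digits on a small fixture,
including the environment component; with naive dummy coding lme4
itself warns of a singular Hessian and returns an arbitrary `s2_e`.

**REML engines.** The default fit optimizes the profiled restricted
likelihood over the log variance ratios `gamma_i = s2_i / s2_eps`
(Nelder-Mead, bounds log gamma in [-16, 16], tolerance 1e-10): the
residual variance has a closed-form profile, and the mixed-model
equations are evaluated with the genotype-by-environment block absorbed
— its coefficient block is diagonal (one entry per observed cell), so
each likelihood evaluation costs one Cholesky of a dense matrix of
order p + g + e (about 165 for a 22 x 47 x 3 trial) instead of order
p + g + e + g*e (about 1200). A classical expectation-maximization
iteration is kept as the transparent reference implementation
(`method="em"`, convergence when every component's relative change is
below 1e-8, cap 2000 iterations, both configurable); its restricted
likelihood is non-decreasing by construction and is asserted so in the
tests. Variance ratios driven to the lower bound are reported as 0
(boundary estimates); EM keeps components non-negative by construction.

BLUPs, their prediction-error covariance (PEV), and the fixed-effect
estimates come from the mixed-model equations at the converged
components. Genotype BLUEs for the Piepho heritability come from a
companion fit with genotype fixed (cell-mean coding) and environment
and GEI random, re-estimated by REML — the standard construction for a
"mean variance of a difference of two BLUEs".

**Likelihood-ratio tests.** Each random term is tested by
-2 logL_R(reduced) + 2 logL_R(full), floored at zero, against
chi-square(1). The null value lies on the boundary of the parameter
space, so the plain chi-square reference is conservative (about half
the statistics are exactly 0; empirical size ~1.6% at nominal 5% on
10 x 8 x 2 null trials); the calibrated 50:50 mixture of a point mass
at zero and chi-square(1) is available via `boundary_correction=True`
(empirical size ~3.6% under the same conditions). The plain reference
remains the default for comparability with common breeding-software
output. Blocks are fixed, so the "block" term reports a Wald F test
and is labelled as such.

## Genetic parameters

With components `(s2_g, s2_e, s2_gxe, s2_eps)`, `e` environments and
`b` blocks:

* `H2 = s2_g / (s2_g + s2_gxe + s2_eps)` — plot basis; the environment
  main effect is excluded, as is conventional when blocks capture the
  within-trial error and environments are a separate stratum.
* `h2_mg = s2_g / (s2_g + s2_gxe/e + s2_eps/(e b))` — genotype-mean
  basis; `e` and `b` are exposed as arguments because under unbalance
  the effective number of environments per genotype is smaller than the
  environment total, which visibly lowers this quantity.
* Cullis: `1 - vd(BLUP) / (2 s2_g)` where `vd(BLUP)` is the mean
  variance of a difference of two genotype BLUPs (the standard
  construction). A second reading — one minus mean PEV over `s2_g` —
  circulates in the literature under the same name; both are computed
  and reported with explicit labels, the pairwise-difference form being
  primary.
* Piepho: `s2_g / (s2_g + vbar/2)` with `vbar` the mean variance of a
  difference of two genotype BLUEs. On balanced data
  `vbar = 2 (s2_gxe/e + s2_eps/(e b))`, making it identical to
  `h2_mg`; the suite checks this equivalence to 1e-6.
* Phenotypic variance is emitted on both the genotype-mean basis
  (`s2_g + s2_gxe/e + s2_eps/(e b)`) and the plot basis
  (`s2_g + s2_gxe + s2_eps`), labelled, since published tables are not
  always explicit about which is printed.
* `CVg = 100 sqrt(s2_g) / mean`, `CVr = 100 sqrt(s2_eps) / mean`,
  ratio `CVg/CVr`; GEI determination
  `r2 = s2_gxe / (s2_g + s2_gxe + s2_eps)`; GEI correlation
  `rge = s2_g / (s2_g + s2_gxe)`. Published tables for the cassava
  series this package mirrors print an `rge` (e.g. 0.56 for fresh root
  yield) that is not consistent with this formula evaluated at their
  other printed components (0.458); we compute the formula value.
* Selective accuracy `rgg = sqrt(1 - mean(PEV)/s2_g)`, clipped to
  [0, 1], undefined at `s2_g = 0`.

The grand mean used for CVs is the fitted intercept; the raw data mean
is also carried in the fit object.

## Stability

The environmental index is `I_j = (mean of available genotype means in
environment j) - (unweighted mean of those environment means)`, so it
sums to zero by construction; under unbalance each environment mean
uses the genotypes present there, and a genotype's own contribution is
not excluded (the classical construction). Per genotype with at least
3 environments, ordinary least squares of its cell means on `I_j`
yields the intercept, slope, `Sdi2 = SSE/(e_i - 2)`,
`R2 = 1 - SSE/SStot` (defined as 0 for a genotype with zero total
variance) and `RMSE = sqrt(SSE/e_i)` (population denominator, so
`RMSE <= sqrt(Sdi2)` always). `Sdi2` is the raw residual variance of
the regression on cell means; no pooled plot-error correction is
subtracted, because the analysis operates on genotype x environment
means rather than plots. Regressions run on raw cell means by default;
the joint-regression identity (genotype-average slope = 1 on balanced
data) is asserted to 1e-6.

## MPS

Rescaling maps each variable linearly onto [0, 100] with 100 at the
desirable end: larger-is-better for yields and `R2`, smaller-is-better
for the plant-architecture score, `Sdi2` and `RMSE`. A constant column
would divide by zero in the raw formula; it is mapped to the neutral
midpoint 50 with a warning so it neither rewards nor penalizes. The
performance axis uses predicted genotypic means (intercept + BLUP),
which are shrunken toward the mean and robust to unbalance; raw means
remain available. MPS is the convex combination of the two axes at
weights (65, 35) by default; the weight sweep runs 0/100 to 100/0 in
5-point steps (21 scenarios), ranks ties by average, and its extremes
equal the pure-stability and pure-performance rankings exactly.

Quadrant groups (productive+stable / stable only / productive only /
neither) compare each genotype's rescaled axes to the genotype mean of
that axis — the mean adapts to the realized spread; median and fixed-50
thresholds are available. Selection differentials report
`Xo, Xs, SD = Xs - Xo, SD% = 100 SD / Xo`.

## MTMPS

The factor model is fitted from the correlation matrix of the MPS
columns: eigendecomposition, Kaiser retention (eigenvalue >= 1,
overridable by an explicit count), initial loadings
eigenvector * sqrt(eigenvalue), varimax rotation with Kaiser row
normalization (delegated to statsmodels' rotation routine, tolerance
1e-10), and a display-only sign convention making each factor's
largest-magnitude loading negative; all distances downstream are
sign-invariant, which the suite checks. Factor scores use the
regression-type estimator `F = Z R^-1 A` with `Z` the
column-standardized MPS matrix (standardization, rather than the raw
0-100 values, is the documented reading of the score equation: it
makes scores scale-free and the ideotype construction coherent). The
ideotype is the row of 100s standardized by the genotype columns' own
means and standard deviations and scored identically. `MTMPS_i` is the
Euclidean distance over retained factors; selection keeps the
`ceil(intensity * g)` smallest (30% of 22 gives 7). Factor
contributions are squared deviations over squared distance; a genotype
exactly at the ideotype gets uniform contributions and a flag. The
gain table assigns each trait to its factor of maximum absolute
loading (ties to the lower index) and reports `Xo, Xs, GS = Xs - Xo,
SG% = 100 GS / Xo` from predicted genotypic means, with a goal-met
flag against the declared trait direction. Published gain tables of
the mirrored series show GS slightly smaller than Xs - Xo (possibly a
heritability multiplier); this package emits its own internally
consistent quantities.

## Associations

Pearson correlations with two-sided t-test p-values among the per-trait
MPS columns (raw means via a flag), no multiplicity adjustment by
default (Bonferroni optional), edges filtered by alpha and |r|. Path
analysis solves `b = Rxx^-1 rxy` on the correlation scale, with
residual effect `sqrt(1 - b'rxy)` and VIF from the diagonal of
`Rxx^-1`; VIF > 10 warns rather than errors.

## Synthetic trials

The generator draws every term of the model independently per trait
and returns the true effects for recovery testing. Default design:
22 genotypes x 47 environments x 3 blocks. Default trait settings
(grand means; `s2_g`, `s2_eps` back-transformed from genotypic and
residual CVs; `s2_gxe` direct) are on the published scale of a
late-stage cassava series for FRY, ShY, DMC, DRY, PH, HI and PIA
(t/ha, %, m and a 1-5 score; PIA is lower-is-better). Two quantities
are not published for that series and are this package's own defaults,
chosen once: the environment variance, `s2_e = 2 s2_g` per trait
(environmental differences across 47 year x locations dominate
genotypic differences, consistent with the large environment mean
ranges the series reports), and the block spread,
`block_sd = 0.5 * s2_eps^0.5` (block differences smaller than
plot error). Block offsets are drawn once per environment and held
fixed, matching the analysis model; their true values are stored.
Unbalance removes whole genotype x environment cells (mirroring clones
dropped between trial years), never single plots, subject to every
genotype keeping >= 3 environments and every environment >= 2
genotypes. Bounded-score traits can be clipped to their scale
(latent-normal then censor); clipping is off by default.

What the generator does *not* emulate: cross-trait genetic correlation
(traits are drawn independently, so the factor structure of simulated
MPS matrices is weaker than in real series, where yield traits
correlate above 0.9 — factor-recovery tests therefore build structured
matrices directly), heterogeneous residual or GEI variances across
environments, non-normal errors, and spatial field trends. Passing
tests on synthetic data demonstrate correctness of the estimators
under the assumed model, not robustness to these departures.

## Problem sizes and numerics used in the tests

Balanced-data equivalences and EM checks run at 10 x 8 x 2; REML
recovery at the full 22 x 47 x 3 design over 20 seeds (components
within 15% on average); test calibration with 500 null trials at
10 x 8 x 2; the boundary-behaviour check at 12 x 24 x 2, where the
information about `s2_g` is large enough for the asymptotic boundary
property to show. Eigen-solves use symmetric LAPACK routines; the
correlation matrix may be ridge-regularized (off by default) when
numerically singular; optimizer tolerances are stated above. Ranks tie
by average; output orderings are alphabetical in genotype identifiers
so runs are byte-reproducible.

## Known limitations

* Single-trait mixed models only: no multivariate REML, no
  factor-analytic GEI covariance structures, no kinship/pedigree.
* Homogeneous residual variance across environments.
* The Eberhart-Russell regression treats cell means as equally precise,
  which under strong unbalance they are not.
* LRT p-values are asymptotic; at these design sizes the plain
  reference is conservative (see above).
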