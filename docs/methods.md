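# Methods

## Model and estimation

The trial design is a randomized complete block experiment replicated
under two phosphorus regimes (stress `NAP`, control `AP`).  For one trait
and one condition the observation model is

    y_ijk = mu + block_j + g_i + e_ijk,
    g_i ~ N(0, sigma_G^2),   e_ijk ~ N(0, sigma^2),

with blocks fixed.  The combined, two-condition model is

    y_icjk = mu + cond_c + block_j(c) + g_i + (gP)_ic + e_icjk,

with a fixed condition effect, blocks nested in condition (coded through
condition-by-block cell dummies), a shared random line effect and an
independent random line-by-condition deviation.  A single residual
variance is assumed across conditions, matching the single residual
column of the reference combined analysis; heteroscedastic residuals are
out of scope.

Variance components are estimated by REML.  The implementation profiles
the residual variance and the fixed effects out of the restricted
likelihood and optimises the variance ratios `gamma_k = sigma_k^2 /
sigma^2` on the log scale (bounded Brent for one ratio, restarted
Nelder-Mead with tolerances 1e-10/1e-12 for two).  All per-iteration
algebra is reduced to the random-effect dimension via the Woodbury
identity, so a 151-line combined fit factors a 453x453 matrix rather than
a 906x906 one.  Ratios that converge to the lower bound (log gamma < -20)
are truncated to exactly zero and flagged as boundary estimates, keeping
truncated components distinguishable from small interior ones.  For
balanced data these REML estimates coincide with the ANOVA
method-of-moments estimators truncated at zero; the tests verify
agreement to 1e-6 relative.

Genotypic values are reported on the observable trait scale as the fitted
grand mean (the average fixed-effect fitted value) plus the line BLUP
`u_hat = gamma Z' W^-1 r`.  BLUPs shrink the raw line means toward the
grand mean by the factor implied by `sigma^2 / r`, and for balanced data
they average exactly to the grand mean.

Random effects are tested by the REML likelihood-ratio deviance
`2 (l_full - l_reduced)` referred to chi-square with 1 df, the convention
of the reference analysis.  Because the null value lies on the boundary
of the parameter space this reference is conservative; the 50:50
chi-bar-square mixture p-value (half the chi-square tail) is attached as
metadata rather than substituted.  The Monte-Carlo acceptance test
confirms an empirical type-I rate at or below the nominal 0.01.

## Genetic parameters

Entry-mean broad-sense heritability is `sigma_G^2 / (sigma_G^2 +
sigma^2/r)` per condition and `sigma_G^2 / (sigma_G^2 + sigma_GxP^2/p +
sigma^2/(rp))` combined, with `r` blocks and `p = 2` conditions.  Values
are clamped to [0, 1] since truncated components can otherwise produce
degenerate ratios.  The reported CV is the residual CV on the genotypic
mean, `100 sqrt(sigma^2) / mean`; this definition reproduces the
reference panel's printed CVs exactly (e.g. 21.79 for lateral root length
under stress).  The stress response is the signed reduction
`100 (AP - NAP) / AP`, negative for traits that increase under
deprivation (root:shoot ratio, root tissue density).

Report tables round to two decimals, matching the reference layout;
internal values keep full precision.  One stored reference value is worth
noting: recomputing the combined stalk-diameter heritability from the
two-decimal components gives 0.2832 against a printed 0.29 — pure
rounding propagation, handled by a one-digit tolerance in the regression
test.  Three truncated residual/interaction entries in the stored
reference table (lateral-root-length and total-root-length control
residuals, root-surface-area interaction) were reconstructed to the full
magnitude implied by their printed heritabilities.

## Synthetic data

The generator draws, per trait, a shared line effect `g_i ~ N(0, var_G)`,
independent condition-specific deviations `(gP)_ic ~ N(0, var_GxP)`,
block effects `N(0, var_block)` per condition-block cell, and i.i.d.
Gaussian residuals, around condition means `mean_AP` and `mean_AP (1 -
reduction/100)`.  This is exactly the combined model's decomposition, so
component recovery is a well-posed check, and it induces cross-over
interaction: the correlation of true line effects across conditions is
`var_G / (var_G + var_GxP)`, which for the reference components yields
the low-to-moderate cross-condition rank correlations seen in such
trials.  Defaults are the reference panel's design (151 lines, 3 blocks)
with its combined-analysis components and condition means; block variance
is unreported in the reference and defaults to `0.25 var_error`, a
magnitude that leaves all downstream estimators unaffected (blocks are
fixed effects).  One root seed spawns an independent stream per trait, so
trait subsets do not perturb each other's draws.  Uniform missing-data
injection is available but off by default (the reference design is
balanced).

What the generator does *not* emulate: observation-level identities
between derived and base traits (each of the 13 traits is simulated
independently; `compute_derived_traits` exists to build
identity-respecting tables from base traits when the collinearity
machinery needs them), non-Gaussian residuals, spatial greenhouse trends,
heteroscedastic residuals across conditions, and seed/maternal effects.
Passing tests therefore certify the estimators under the model's own
assumptions, not robustness to violations of them.

## Correlations, collinearity, diversity

Pearson correlations are computed between per-condition BLUP vectors with
two-sided t-test p-values, flagged at alpha = 0.01 without multiplicity
correction (matching the reference analysis); Spearman correlations use
average ranks for ties (BLUPs essentially never tie).  VIFs are the
diagonal of the inverse trait-correlation matrix; exact dependencies are
detected through the eigenvalue spectrum (relative cutoff 1e-12) and
reported as infinite.  Pruning removes, at each step, the trait with the
largest VIF maximized over the two conditions, with alphabetical
tie-breaks — the removal order is not specified in the reference, and the
joint-max criterion enforces its stated outcome (identical discard sets
under both conditions) by construction.  The eight-trait set retained in
the reference trial ships as the `reference8` preset so diversity and
index stages can reproduce that trait selection on new data.

Distances are root-mean-square differences over standardized traits
(dividing the squared Euclidean distance by the trait count), the form
consistent with the small fusion levels reported for such panels and
invariant to duplicating traits.  UPGMA uses size-weighted average
linkage (scipy's implementation, verified against a brute-force O(n^3)
agglomeration oracle).  The Mojena cutoff is `mean + k sd` of the fusion
levels with `k = 1.25` (Milligan-Cooper) by default and an n-1 sd; the
reference reports only the resulting cutoff, not its constant.  Merges
exactly at the cutoff are kept.

## Selection indices

Relative trait values are stress BLUP / control BLUP, guarded against
near-zero denominators at 1e-8 relative to the column scale.  PCA is an
eigen-decomposition of the correlation matrix of the standardized inputs;
components with eigenvalue >= 1 (Kaiser) are retained; contribution rates
divide by the total variance (the trait count), not the retained
variance.  Eigenvector signs are arbitrary, so each component is oriented
to make its loading sum positive — for predominantly positively
correlated trait sets this makes "bigger under stress" score positively.
Quadrant thresholds sit at zero (the standardized mean); exact zeros fall
on the sensitive/poor side.  The combined top-k rule is the rank-sum of
the two index rankings with alphabetical tie-breaks; single-index
rankings are available from the returned table.  Whether PCA uses the
correlation or covariance matrix is immaterial after standardization.

## Problem sizes and numerical choices

The bundled tests run the full design size where it matters (200
simulated 151-line panels for variance-component recovery, 500 replicates
for the LRT error rates at a 40-line design, 100 random 8-leaf matrices
for the UPGMA oracle) and small panels (20-60 lines, 2-4 traits)
elsewhere; the complete suite runs in well under a minute on one core.
Degenerate inputs are handled explicitly: zero-variance traits are
rejected by standardization with the trait named, zero denominators in
derived traits become missing values rather than infinities, and a
constant trait makes its correlation and VIF entries undefined (NaN /
error) rather than silently zero.

## Known limitations

- Single residual variance in the combined model; no pedigree, spatial or
  multi-year covariance structures.
- No standard errors or confidence intervals for heritabilities.
- Subgroup structure within diversity clusters has no defined rule and is
  not computed; bootstrap support values are out of scope.
- Panel-level outcomes of the reference trial that depend on its raw data
  (exact cluster counts, quadrant group sizes, index correlations) are
  checked as qualitative properties on simulated panels, not as numeric
  regressions.
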