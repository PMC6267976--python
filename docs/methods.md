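# Methods

This note documents the models implemented in `cwmcats`, the defaults and
tolerances that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where more than one reasonable option
existed.

## Data model

Abundance matrices carry an explicit `kind` (`cover` percent, `count`, or
`relative`). Relativization divides each row by its total; rows with zero
total are retained and flagged rather than dropped, because "no emergence"
is an observation that downstream stages must exclude deliberately (CWMs
for such rows are NaN, distance computations reject them). Relative rows
must sum to 1 within 1e−9 absolute — ample for float accumulation at
≤ ~100 species. Trait tables require positive seed mass (mg) and specific
root length (m g⁻¹) and a Julian flowering date in [1, 366]; missing trait
values are a hard error, not an imputation target.

## CWM trait–environment models

Each CWM trait is modelled as

    CWM ~ s(soil pH, k = 10) + s(pine basal area, k = 10)

with Gaussian errors: cubic B-spline bases with basis dimension 10 per
term (the cap on each smooth's flexibility), a second-derivative
smoothness penalty, and per-term penalties chosen by generalized
cross-validation. GCV is minimized over the two log-penalties by
Nelder–Mead capped at 150 evaluations; the criterion surface is smooth and
nearly unimodal at this problem size, so the cap costs nothing in
accuracy. Refits on identical data are bit-reproducible (deterministic
optimizer, deterministic start).

Reported per-term tests are Wald tests conditioned on the selected
penalties, labelled approximate for that reason. The adjusted R² uses the
effective degrees of freedom of the penalized fit:
1 − (RSS/(n − edf)) / (TSS/(n − 1)).

**Extrapolation.** B-spline bases are undefined beyond their boundary
knots, so predictions outside the calibration range are clamped to the
nearest range edge, flagged on the returned value, and announced with a
warning. Constant extension is deliberately conservative: a penalized
spline carries no information beyond its data. Predicting at basal area
0 or 59 m² ha⁻¹ when the quadrat draws only approach those edges therefore
uses the fitted value at the nearest observed environment. Both the
full-sun convention (BA = 0) and a glasshouse-equivalent intermediate
(e.g. BA = 30) are plain inputs; neither is privileged.

Fits serialize to JSON (trait name, penalties, coefficients, training
ranges, and the training predictor matrix from which the spline basis is
rebuilt deterministically), so calibration and prediction can run as
separate CLI steps with bit-identical predictions.

## Maximum-entropy abundance prediction

The CATS solution maximizes H(p) = −Σ p_i ln p_i subject to the CWM
equality constraints and the simplex constraints. We solve the convex dual
min_λ log Z(λ) − λ·T̄ (log-sum-exp stabilized) with damped Newton steps:
the gradient is the constraint residual and the Hessian the trait
covariance under p, with a 1e−12-scaled ridge so steps stay defined when
the solution approaches a face of the simplex. Convergence is declared at
max residual ≤ 1e−8 in standardized trait units (default budget 10 000
iterations; typical problems converge in < 30).

Trait columns are z-standardized over the problem's species pool before
solving. The solution is provably invariant to affine rescaling of any
trait column (tested), but standardization makes one tolerance meaningful
across mg, m g⁻¹ and Julian days. The prior is uniform by default — the
classical unweighted maxent; a species-pool abundance prior is accepted
but off by default.

**Feasibility.** A target T̄ is attainable iff it lies in the convex hull
of the pool's trait vectors. Membership is decided exactly by linear
program; infeasible targets get a Euclidean projection onto the hull
(computed in the working trait space by SLSQP on the simplex) and its
distance. `solve_maxent` raises by default on infeasible targets, carrying
the projection report; `on_infeasible="project"` substitutes the nearest
attainable constraints and records the distance in the solution, which the
pipeline logs per treatment — silent projection would mask calibration
pathologies, but calibrated constraints routinely land slightly outside
the hull of a small species pool, so the pipeline makes the projection an
explicit, inspectable choice. Note that a projected target lies on a hull
face, so species off that face receive zero predicted abundance; this is
the correct constrained optimum, not a numerical artifact.

## Fit evaluation

* `r2`: squared Pearson correlation over all flattened treatment × species
  cells of untransformed relative abundances.
* `rmse_sqrt`: RMSE of square-root-transformed relative abundances,
  bounded in [0, 1] for simplex rows.

Significance comes from permuting the observed matrix with predictions
fixed. The default scheme permutes species entries independently within
each treatment row — it preserves every treatment's abundance profile
while destroying species identity, which is the hypothesis at stake; the
alternative (permuting whole rows) is exposed as `scheme="rows"`. The
p-value includes the observed statistic in the null set,
p = (1 + b)/(1 + m), which guarantees validity and makes 1/(m+1) the
attainable minimum (0.001 at 999 permutations). "At least as extreme"
means ≥ for r2 and ≤ for rmse_sqrt, with a 1e−12 tie guard.

Treatment means are computed over non-empty pots only. Dominance accuracy
reports, per treatment, whether the predicted argmax species matches the
argmax of the observed treatment mean, and the fraction of individual
non-empty pots whose own dominant is the predicted one; ties in observed
maxima count as hits when the predicted dominant is among the tied set.

CWM concordance is per-trait Pearson correlation across treatments with
the classical t-distribution p-value (requires ≥ 3 treatments).

## Two-way PerMANOVA

Distances: Bray–Curtis Σ|x−y|/Σ(x+y) for community matrices (undefined
and rejected for all-zero rows), Euclidean for univariate responses. The
total sum of squared dissimilarities is partitioned through the
Gower-centered inner-product matrix G = −½ C D² C using sequential
(Type I) projection matrices for A, B, A×B — A entered first; for the
balanced and near-balanced designs this package targets the order is
essentially immaterial, and the projection formulation does not require
balance (17/17/16/16 replicates are handled exactly). Pseudo-F is
(SS_term/df_term)/(SS_res/df_res); p-values come from free permutation of
samples (rows and columns of D together, 999 by default), recomputing
every term's pseudo-F, with the observed value included in the null set.
With Euclidean distances on one variable this reproduces classical
sequential two-way ANOVA F exactly (McArdle–Anderson identity, verified to
1e−8 against statsmodels and to 1e−6 against vegan's adonis2 in the test
suite).

## Synthetic data generator

The generator supplies both pipeline stages with data whose generating
mechanism is known, at the original study's dimensions: 96 quadrats across
pH ∈ [5.5, 7.5] and pine basal area ∈ [0, 59] m² ha⁻¹; 79 species; a 2×2
light × parent-material experiment with 17/17/16/16 pots and 12 seeds per
species per pot, evaluated at (pH 6.8, BA 0), (5.9, 0), (6.8, 59),
(5.9, 59).

Species fitness follows a Gaussian kernel on a standardized trait scale,
with per-trait optima moving linearly in (pH, BA); the slope signs make
seed mass fall with pH and rise with basal area while SRL and flowering
date do the opposite, matching the qualitative trait–environment structure
of this vegetation type. `filter_strength` (kernel sd, default 0.8 z
units) controls how hard the environment filters; seed mass and SRL are
lognormal across the pool, flowering date normal. Quadrat cover is a
Dirichlet draw (concentration 200/`noise_overdispersion`) around the
fitness-proportional expectation, scaled to a random total cover of
40–95%. Greenhouse emergence is Binomial(12, 0.7 × fitness at the
treatment's environment), independent across species — a sowing
experiment with near-total post-emergence survival and no competition,
which is exactly the regime the experimental design isolates. The first
five species sit at fixed, spread-out trait anchors (a sun specialist, a
shade specialist, three intermediates) so the experiment has distinct,
treatment-dependent dominants; an `opening_fraction` parameter can pin a
share of quadrats to BA = 0 (grass openings), default 0.

**What it does not emulate.** Real quadrats vary in ways the kernel does
not model: unmeasured environmental heterogeneity, spatial autocorrelation,
dispersal limitation, biotic interactions, observer error in visual cover
estimates. Consequently the synthetic CWM–environment fits are much
cleaner (adjusted R² ≈ 0.9+) than trait–environment models fit to field
data (≈ 0.2–0.4). Passing the recovery tests therefore demonstrates that
the algorithms recover known structure at realistic dimensions and noise
of the modelled kind — not that field predictions reach this accuracy.

## Problem sizes in the tests and acceptance script

End-to-end recovery uses 10 landscape seeds; surface recovery 10
landscapes × 3 traits; the maxent oracle 100 random problems (S ≤ 4,
J ≤ 2) against an exhaustive exactly-feasible simplex grid (free simplex
coordinates on a 4e−3 grid with the constrained coordinates solved
linearly, twice refined ×25, seeded from a feasible LP point); both
permutation tests are calibrated over 500 null simulations at 99
permutations each (p granularity 0.01 is ample at α = 0.05). These sizes
keep the full suite to a couple of minutes while leaving the checks
statistically meaningful.

## Known limitations

* Only Gaussian-error additive models with two smooth predictors; no
  interaction smooths, non-Gaussian families, or spatial terms.
* Maxent handles equality constraints only (no inequality or hierarchical
  CATS variants) and assumes the trait matrix has no NaNs.
* PerMANOVA offers free permutations only — no strata/blocks, and no
  dispersion (PERMDISP) companion test.
* The original study's data tables are journal supplements and not
  redistributed; analyses of those data run only when the user supplies
  the files (see `tests/test_acceptance.py` for the expected layout).
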