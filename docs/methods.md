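# Methods and design notes

## Model

The outcome is gestational weight gain (weight at age `t` minus
pre-pregnancy weight, kg), shifted by +20 kg so it is strictly positive,
and modeled per pre-pregnancy BMI group with a Box-Cox *t* (BCT)
distribution whose four parameters are smooth functions of gestational age
on [0, 45] weeks:

- `mu(t)` — median of the shifted gain; identity link; degree-3 B-spline
  regression (unpenalized) with internal breakpoints at 12, 20, 28 and 34
  weeks by default, boundary knots at the domain edges.  8 coefficients.
- `sigma(t)` — approximate coefficient of variation; log link; cubic
  penalized spline, default 3 effective df.
- `nu(t)` — Box-Cox skewness power; identity link; default 2 df.
- `tau(t)` — *t* degrees of freedom (kurtosis); log link; default 2 df.

The BCT density is the standard truncated form: the Box-Cox transform of
`y/mu` scaled by `sigma` follows `t(tau)` renormalized by the *t*-mass of
the feasible transform range, `T_tau(1/(sigma*|nu|))`, so the density
integrates to one on `(0, inf)` exactly for any `nu`.  For chart-realistic
parameters the truncation mass is ~1e-10 or less; the implementation
carries it exactly, which matters only for the engine's own invariants
(propriety of the density, exact quantile inversion).  `|nu| < 1e-6`
routes to the log branch of the transform to avoid catastrophic
cancellation.

Two z-scores are exposed: `z_raw`, the *t*-scale transform itself, and
`z_normal = Phi^-1(F(y))`, the normal-equivalent score.  Centile labels
are defined on the normal scale (P2.3 ↔ −2 SD, P16 ↔ −1 SD, P50 ↔ 0, P84
↔ +1, P97.7 ↔ +2), which is the only scale on which "percentile = SD"
statements are coherent.

## Data preparation

- **WHO BMI groups** partition (0, ∞) with half-open boundaries
  [18.5, 25), [25, 30), [30, 35), [35, 40), [40, ∞); printed one-decimal
  ranges leave gaps on a continuum, so e.g. 24.95 is classified normal.
- **Window selection** keeps at most one measurement per window: early
  (6–19.9 wk, closest to 13), mid (20–31.9, closest to 26), late (32–45,
  closest to 40).  Equidistant ties go to the earlier measurement
  (deterministic; the choice is otherwise arbitrary).
- **Week-0 nudge.** Every woman contributes a week-0 row whose gain is
  identically zero; a zero-variance outcome breaks the likelihood.  Each
  week-0 gain is replaced by a draw from N(0, 0.98 kg²) — the variance of
  a difference of two weighings each with a 0.70 kg dial error.  The
  nudge RNG uses one stream per run; the seed is recorded in the fit
  metadata (library default 20090401).
- **+20 kg offset** is applied after nudging; rows with `y = gain + 20 <= 0`
  are dropped and counted (none occur at realistic gains; −20 kg is an
  extreme lower bound for weight change in pregnancy).
- **Uncomplicated subset**: women whose four complication flags
  (hypertensive disorder, diabetic disorder, preterm birth, SGA/LGA
  infant) are all known and false.  Unknown flags exclude a woman from
  this subset only, never from the full fit.

## Fitting

Rigby–Stasinopoulos (RS) backfitting: cycle over the four parameters; for
each, form the working response `eta + u/w` from the score `u` of the
log-likelihood on the link scale and weights `w`, then solve one penalized
weighted least-squares problem.  Implementation choices:

- **Weights.** Expected information for mu and sigma
  (`(tau+1)/((tau+3) mu^2 sigma^2)` and `2 tau/(tau+3)` on the log scale);
  squared scores (quasi-Fisher) for nu and tau, floored by a small
  stabilizer.  The working-response ratio `u/w` is *not* clipped
  per-observation: clipping biases the aggregate step direction under
  squared-score weights (observed as a stall against the direct-MLE
  oracle during development).
- **Score of the truncation mass** is omitted (it is ~1e-10 at fitted
  magnitudes); the exact mass *is* in the objective, and step-halving
  against that objective keeps the iteration honest regardless.
- **Step-halving.** Every coefficient update is accepted only if the
  penalized objective (deviance + quadratic penalties) does not increase;
  otherwise the step is halved up to 12 times and then rejected.  The
  objective is therefore non-increasing by construction.  The raw
  deviance is recorded alongside; with penalties present only the
  penalized objective is guaranteed monotone, so the monotonicity
  invariant is asserted on it.
- **Smoothing constants** are chosen so the trace of each smoother equals
  the requested df, re-solved during the first three outer cycles and
  then frozen (weights change little afterwards and a fixed constant
  gives a well-defined objective).  The penalty is the exact Gram matrix
  of basis second derivatives (per-interval Simpson, exact for the
  piecewise-linear `B''` products), whose null space is exactly the
  affine functions for any knot layout; `df = 2` therefore degenerates to
  an affine curve and `df = 1` to a constant (intercept-only basis).
- **Initialization.** mu from an unweighted least-squares B-spline fit of
  `y`; sigma constant at the MAD of those residuals over the median of
  `y` (clipped to [0.01, 0.5]); nu = 1; tau = 10.  A trend-contaminated
  sigma start (e.g. pooled MAD of `y`) can send the fit to a spurious
  high-`nu` mode; the residual-based start avoids it.
- **Convergence**: |Δ global deviance| < 1e-3 across an outer cycle, max
  50 cycles; non-convergence is reported honestly in the chart metadata,
  never masked.
- **Guard rails** at evaluation: sigma ∈ [1e-4, 2], tau ∈ [0.2, 1e6],
  nu ∈ [−8, 8] on the link scale.  They never bind at realistic fits.
- **BIC** = deviance + ln(n) · (8 + df_S + df_L + df_T).  The linear
  baseline is an OLS fit of gain on age with Gaussian likelihood and 3
  parameters.  Because the +20 kg shift has unit Jacobian, deviances on
  the shifted and unshifted scales are directly comparable.

## Chart deliverables

The parameter grid holds (mu, sigma, nu, tau) at integer weeks 0–42 at
full precision (rounding only in display formats).  Z-scores at exact
decimal ages interpolate each parameter linearly between bracketing weeks
— interpolating parameters rather than quantiles keeps the calculator and
the centile curves mutually consistent.  Ages in (42, 45] extrapolate the
terminal week pair linearly, with a warning.  The calculator refuses
`gain <= -20` (outside the model's support).

IOM ranges are treated as closed intervals (boundary = adequate); the
three obesity grades share the 5–9 kg range.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
not any real population:

- per-woman BMI uniform within her group (obesity grade 3 capped at 50
  kg/m², the unbounded WHO class needs a cap), height ~ N(1.65 m, 0.07)
  truncated to [1.40, 1.95] m, pre-pregnancy weight = BMI · height²;
- median-gain truth per group: a shape-preserving cubic through (0, 0)
  and the group's anchors at 20 and 40 weeks, with the derivative at
  conception set to half the 0–20-week secant (slower first half) and a
  linear continuation past 40 weeks; S/L/T truths are constants
  (sigma 0.06, nu 0.8, tau 12) — invented but realistic magnitudes,
  config-exposed; recovery tests assert recovery of whatever truth is
  configured;
- one gestational age per non-missing window (uniform over 6–19.9,
  20–31.9, 32–42; no missingness by default), true gain = the BCT
  quantile of a single woman-level uniform shared across her windows
  (realistic within-woman tracking while every cross-sectional margin
  stays exactly BCT, matching the cross-sectional fit), plus a fresh
  N(0, 0.70²) dial error per observed weight;
- Bernoulli complication flags (defaults 8% hypertensive, 5% diabetic,
  6% preterm, 20% SGA/LGA — typical cohort-study magnitudes).

What the generator does **not** emulate: cohort heterogeneity in
measurement protocols, self-reported vs measured weight provenance,
real-world BMI-group prevalence, gestational-age dating error, or
correlated complication risks.  Passing recovery tests therefore show the
estimator is consistent under the model's own assumptions plus
measurement noise — not robustness to those real-data features.

## Diagnostics

- **Worm plots**: equal-count age bins (week-0 rows form their own bin
  when above 10% of the data — they are a point mass in age); within each
  bin, ordered normal-equivalent residuals against Blom order-statistic
  medians, detrended, with 95% pointwise bands
  `1.96 sqrt(p(1-p)/n) / phi(z_p)`.
- **Q statistics**: per equal-count age group, standardized departures of
  the residual mean (`m sqrt(n)`), variance (Wilson–Hilferty cube-root),
  skewness and kurtosis (D'Agostino z-transformations); Q = sum of
  squares, referred to chi-square with (groups − curve df, floored at 1)
  degrees of freedom, pairing mean↔M, variance↔S, skewness↔L,
  kurtosis↔T.  Groups under 10 observations withhold the p-value.
- **Coverage**: empirical fraction of observations below each nominal
  centile, via the same interpolation as the calculator.
- **Subgroup screen**: across-subgroup sample variance (ddof 1) of fitted
  median gains per week, compared against the 0.98 kg² measurement-error
  variance — subgroups whose spread stays below it are practically
  indistinguishable.

## Known limitations and problem sizes

- With the default df the S-curve cannot fully absorb the sharp change in
  relative spread near week 0 created by the nudge point mass plus
  measurement error; worm plots and mean/variance Q statistics flag this
  early-pregnancy misfit even when coverage is calibrated (see
  `examples/diagnostics_report.py`).  Raising the S-curve df softens it;
  model choice is deliberately manual, by diagnostics.
- Smoothing amounts are fixed df, not estimated; no within-woman
  correlation structure; no covariate adjustment beyond BMI group.
- Default problem sizes — 5,000 women for single-group recovery studies,
  2,000 per group for the six-group pipeline, 200 replicates for the
  Q-statistic null calibration — give Monte-Carlo error comfortably below
  every asserted tolerance while a full test run stays in the minutes
  range.
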