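# Methods

## The model

All computations rest on the asymptotic exponential (two-pool) decay
curve for the remaining dry-mass fraction of a litter bag,

    m(t) = a·e^(−k·t) + (1 − a),

with decomposable fraction `a` (dimensionless), rate `k` (day⁻¹) and
asymptote `1 − a`. Time is in days everywhere; mass is always a fraction
of the initial dry mass, so `m(0) = 1` by construction and the intercept
is never a free parameter.

The Tea Bag Index reads this curve through a three-fraction lens: a
labile pool that decomposes at rate `k`, a stabilised pool formed from
incompletely digested hydrolysable material, and a recalcitrant
(acid-unhydrolysable) pool assumed inert on the ~90-day incubation
timescale. Its closed forms are

* stabilisation factor `S = 1 − loss_green / H_green`,
* rooibos decomposable fraction `a_r = H_rooibos · (1 − S)`
  (stabilisation is mathematically treated as instantaneous),
* rate inversion `k = ln(a_r / (m − (1 − a_r))) / t`,
* mass margin `MM = 100 · (m − (1 − a_r))` in percent of initial dry
  mass.

The hydrolysable fractions default to `H_green = 0.842`,
`H_rooibos = 0.552` (the standard chemical parameterisation of the two
teas). They are configuration values (`TBIConstants`, or `h_green` /
`h_rooibos` in the text config), never inlined in formulas, so
alternative parameterisations can be swapped in.

## Sign conventions and degenerate inputs

* `S` may be negative (green tea lost more than its hydrolysable pool);
  it is preserved and flagged `NEGATIVE_S`, never clamped, because
  negative values are diagnostic of recalcitrant-pool decomposition.
* `MM` is remaining minus asymptote; positive means the bag has not
  reached its asymptote. Negative margins are returned as-is.
* The elementary inversion raises `AsymptoteReachedError` (carrying the
  margin) when `m ≤ 1 − a_r`; the aggregated pair computation instead
  reports `k_tbi = None` with the `ASYMPTOTE_REACHED` flag, so messy
  field tables process without exceptions.
* A rooibos bag that gained mass (`m > 1`) is flagged `MASS_GAIN` and
  assigned the no-loss boundary `k = 0`; a green bag that gained mass is
  treated as zero loss (`S = 1`, the entire pool stabilised) and flagged,
  keeping the `S ≤ 1` invariant while leaving the anomaly visible.
* Pairing requires matching tea types and equal incubation days; a
  configurable `day_tolerance` (default 0) absorbs retrievals that differ
  by a day. The rooibos day is the one used for the inversion and window
  check.

## Curve fitting (`fit_decay`)

`k_real` and `asymptote_real` come from bounded trust-region nonlinear
least squares (scipy `least_squares`, method `trf`, analytic Jacobian)
over `a ∈ [10⁻⁶, 1 − 10⁻⁶]`, `k ∈ [10⁻⁸, 10]` day⁻¹, tolerances 10⁻¹²
on cost, step and gradient. Initialisation is deterministic: `a₀ =
clamp(1 − min(m), 0.05, 0.95)` and `k₀` from an origin-constrained
log-linear regression of `−ln((m − (1 − a₀))/a₀)` on `t` (fallback
0.01 day⁻¹). Because a single start can land in a local minimum on noisy
short series, a fixed 3×3 grid of additional starts
(`a₀ ∈ {0.2, 0.5, 0.8} × k₀ ∈ {0.003, 0.02, 0.1}`) is always tried and
the lowest-cost solution kept — still fully deterministic, so identical
input gives bit-identical output.

A fit is *successful* when the solver converged, both parameters are
interior to their bounds, the series has ≥ 4 points, and the relative
standard error of `k` (from the Gauss–Newton covariance) is below 100 %
(configurable via `max_k_rel_se`). Constant or net-mass-gaining series
short-circuit to `UNIDENTIFIABLE`; numeric failures are recorded, never
raised. Weighted/heteroscedastic and free-intercept variants are out of
scope.

`fit_margin` evaluates the *fitted* curve at the requested day (so the
margin is defined between observation days); a nearest-observation mode
is available.

## Diagnostics

A pair is *usable* when none of `NEGATIVE_S`, `LOW_MASS_MARGIN`
(MM ≤ 10 % by default), `OUT_OF_WINDOW` (incubation outside 45–135 days)
or `ASYMPTOTE_REACHED` is raised; `MASS_GAIN` alone is reported but not
blocking. Flags are monotone in their thresholds by construction. The
green-tea margin is reported but not used for usability (it is ≈ 0 by
construction at pair level); a `strict_green` mode additionally requires
|MM_green| ≤ 5 %.

The asymptote-transfer model is a plain OLS regression of the rooibos
asymptote on the green asymptote (both as remaining-mass fractions, not
S values), reporting slope, intercept, R² and F on (1, n − 2) df. The
predicted-vs-observed comparison reports RMSE, mean bias and the OLS
line of predicted on observed — a deliberate choice over major-axis
methods, since the reference of interest is the 1:1 line — plus bias and
RMSE within mass-margin bins with edges at 5 % and 10 % (configurable).
`predict_k_variants` produces the three candidate rates per pair
(S-derived, observed-asymptote, transferred-asymptote); a variant whose
asymptote is already reached is `None` and named, never dropped
silently.

## Synthetic generator

The forward model is the three-fraction structure itself:

    m(t) = a_labile·e^(−k_labile·t) + s_stabilised
         + r_recalcitrant·e^(−k_recalcitrant·t) + ε,  ε ~ N(0, σ²) i.i.d.

with the pool fractions constrained to sum to 1. `k_recalcitrant = 0`
recovers the exact two-pool TBI model (the conformant case);
`k_recalcitrant > 0` produces the assumption violation in which
"recalcitrant" material leaks from the start, which is what makes short
fits read high on both asymptote and rate. Noise is additive Gaussian on
the remaining fraction — a laboratory balance-error model consistent
with percent-of-initial-mass reporting — truncated to (0, 1.2];
multiplicative noise is deferred. A day-0 sample is pinned to exactly 1.
Gradual (non-instantaneous) stabilisation is a known extension, not
implemented.

What the generator does *not* emulate: leaching pulses, fragmentation
losses, mesh-size effects, temperature/moisture covariates, or serially
correlated measurement error. Passing recovery tests therefore shows the
estimators are correct under the stated error model, not that field data
meet that model.

Default designs: lab-like `{7, 14, 21, 28, 42, 60, 75, 90}` days and
sparse `{30, 60, 90, 120}` days. Default study conditions used in tests
and the acceptance script: conformant rooibos `a = 0.45,
k = 0.012 day⁻¹, σ = 0.005` (typical of laboratory incubations, where a
0.5 % of initial mass weighing error is realistic); the
leaky-recalcitrant scenario `a = 0.3, k = 0.05, r = 0.3,
k_rec = 0.002 day⁻¹`, sampled every 5 days to 120.

## Monte-Carlo and cohort designs

* Parameter recovery: 200 replicate series per condition; means of
  successful fits are compared with truth (5 % for k, 2 % for a).
* Mass-margin bias gradient: cohorts built with a true rooibos asymptote
  of 0.55 and an S-derived asymptote overestimating it by 0.02; the true
  rate per cohort places the harvest-day TBI mass margin at 3 %, 8 % or
  20 %; 200 noisy pairs each. The absolute bias of `k_TBI` falls
  steeply with margin — analytically the error term is
  `ln((a − δ)/(a·e^(−kt) − δ)) − kt`, which diverges as the margin → 0.
* Designed retention cohort: 500 noiseless conformant pairs with
  `S* = 0.2` and `k ~ U(0, 0.03)` day⁻¹; the MM > 10 % rule then retains
  the closed-form fraction `ln(4.416)/(0.03·90) ≈ 55.0 %`, checked
  within a binomial 95 % interval.
* Bulk round-trip exactness is asserted on `a ∈ [0.2, 0.95],
  k ∈ [10⁻³, 0.05] day⁻¹, t ∈ [5, 100] d` (`kt ≤ 5`). This is the
  realistic field domain; far beyond it (`kt ≫ 5`) the subtraction
  `m − (1 − a)` is dominated by floating-point cancellation and no
  inversion can be exact to 10⁻¹⁰, which is a property of float64, not
  of the estimator.

## Numerical choices

* Ties between equal-cost starts resolve to the first in a fixed order.
* Per-series seeds in the CLI derive from `crc32(f"{seed}:{id}")`
  masked to 31 bits, so one run seed reproducibly governs all series.
* CSV dialect is fixed (comma, `.` decimal, UTF-8, LF, header
  required); percentages are serialised on the 0–100 scale in `_pct`
  columns. One strict dialect with clear line-numbered errors was
  preferred over delimiter sniffing.

## Known limitations

* The success criteria for a fit are this package's own explicit rules;
  published analyses rarely state theirs, so counts of "successful fits"
  need not match other software.
* No mixed-effects or environmental-covariate modelling; no long-term
  (multi-year) prediction — the two-pool model is explicitly a
  short-incubation description.
* Transfer of `k` (as opposed to `S`) across litter types is
  deliberately unsupported.
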