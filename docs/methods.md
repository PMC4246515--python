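# Methods

## Model and assumptions

Leaf elongation is modelled as determinate growth on a thermal-time clock:
the beta sigmoid function (README for the closed form) has exactly zero
elongation rate at the start (`t0`) and end (`te`) of growth and a single
rate maximum at `tm`. The assumptions this buys, and their limits:

- Growth is a single uninterrupted episode. Regrowth after cutting, or
  biphasic responses to stress, are out of scope.
- Thermal time is an adequate clock: daily mean temperature excess over a
  species base temperature, summed, with negative daily contributions
  clipped to zero (the standard growing-degree-day convention — below the
  base the plant does not grow or grows very slowly). Sub-daily records
  are aggregated to daily means first. The base temperature is a
  per-dataset configuration value (10 °C is typical for maize, 8 °C for
  Miscanthus); day-equivalents of thermal-time results are reported only
  when a constant chamber temperature and base are configured, since only
  then is °Cd/day a constant.
- Beyond `te` the leaf holds its final length `Lm` exactly (plateau rule);
  before `t0` the length is exactly zero.

Cell-length profiles reuse the same shape with a free basal level `Lb`,
because dividing cells have a non-zero length before elongating. The leaf
base is fixed at position zero (no free basal-position offset). Division
zone = basal stretch where the fitted curve stays at or below a threshold
(default 40 μm, the conventional dividing-cell cutoff, configurable);
elongation zone = from there to `Pe`. The threshold must lie strictly
between `Lb` and `Lm` or the zone is undefined and reported as an error.

Weibull (`Lb + (Lm−Lb)(1−exp(−(x/λ)^k))`), Gompertz
(`Lb + (Lm−Lb)exp(−exp(−k(x−x0)))`) and logistic
(`Lb + (Lm−Lb)/(1+exp(−k(x−x0)))`) alternatives share the asymptote
semantics, so their R² values are directly comparable with the beta fit.
On beta-generated data they fit almost — but not exactly — perfectly
(R² > 0.99), mirroring how close these families are on real cell-length
data; the beta form is preferred because its parameters are the
biologically meaningful ones.

## Fitting

Per-leaf bounded nonlinear least squares (scipy's trust-region reflective
solver), minimising the sum of squared residuals in measurement units.

- Starting values from the data: `Lm₀ = 1.05·max(L)`; `te₀` = first time
  the series reaches 95 % of its maximum; `tm₀` = midpoint of the
  steepest finite-difference interval; `t0` fixed at 0.
- `t0` is fixed at the sowing origin by default because freely estimated
  values are frequently negative and biologically meaningless for
  seedlings; `FitOptions(fix_t0=False)` releases it (useful when growth
  demonstrably starts late, e.g. regrown tillers).
- Ordering constraints (`tm < te`, `Pm < Pe`) are enforced structurally by
  optimising the positive increment `dte = te − tm` inside box bounds
  `Lm ∈ (0, 10·max L]`, `tm ∈ (0, 2·t_last]`, `dte ∈ (0, 2·t_last]`.
- Convergence tolerance 1e-10 (relative, on cost and step), at most 200
  iterations per parameter. On failure the fit restarts from a fixed
  sequence of up to five ±20 % perturbations of the starting values; the
  best SSE wins, and a fit that never succeeds is returned flagged
  `converged=False` with the reason — a batch never aborts on one leaf.
- R² is the centred coefficient of determination (1 − SSE/SStot about the
  observed mean). Constant series have undefined R² and are rejected as
  degenerate before fitting.
- Replicates of a group can be pooled into one joint series
  (`pool_series` / `--pool-groups`), averaging coincident time points;
  per-leaf fitting remains the default since it is what gives valid
  per-parameter means, standard errors and group tests.

Known fitting limitations, deliberate:

- Ordinary (unweighted) least squares. Cell-length scatter grows with
  distance from the leaf base, and the first ~3 mm of the division zone
  sit slightly above the fitted curve (the basal hyperbolic deviation);
  neither is modelled or corrected.
- `te` (and hence everything derived from it) is poorly constrained when
  the series stops before the plateau; measure until growth has ceased.

## Derived parameters

All secondary quantities come from the fitted curve, not from the raw
points: LERmax from its closed form (verified against the analytic
derivative and a dense grid), timing points by bracketed root finding
(brentq, abscissa tolerance ~1e-12) on the strictly monotone curve
segments, steady-state windows by root finding on each flank of the rate
maximum, LEDs as exact differences of the named time points. The default
derived set is t20 %, t50 %, t90 %, t100 mm, LED(100−e), LED(20 %−90 %),
LED(20 %−e) and the 90 %/95 % steady-state windows; every piece is
configurable (fractions, absolute milestones, LED pairs, window fractions,
zone threshold). An absolute milestone beyond a leaf's final length is
omitted with a logged warning rather than failing the batch — essential
when genotypes of very different sizes share one configuration.

## Group statistics

Two groups: two-sided Student's t-test with pooled variance
(df = n₁+n₂−2), plus the percent difference of means relative to the first
(control) group; Welch's correction behind a flag. Three or more: one-way
ANOVA, then Scheffé pairwise contrasts
(`F_ij = diff² / (MSE (1/n_i + 1/n_j)) / (k−1)` against F(k−1, N−k)),
summarised as a compact letter display built by insert-and-absorb over the
significant-difference graph. Scheffé protects all contrasts
simultaneously and is therefore conservative relative to unadjusted
pairwise tests. No multiple-testing control is applied across the many
derived parameters; treat per-parameter p-values accordingly.

## Synthetic data

The generator draws beta-sigmoid curves at a sampling schedule and adds
noise: additive Gaussian for leaf length (ruler error, default sd 5 mm,
~1 % of a mature maize leaf — consistent with the R² ≈ 0.997–0.999 regime
daily measurements produce), multiplicative Gaussian for cell lengths
(default cv 0.25, because adjacent-cell scatter scales with cell size and
at that level refits land in the R² ≈ 0.75–0.95 band seen on real
profiles). Cohorts add between-plant parameter jitter (cv 3 %, which at
n = 9 reproduces standard errors of a few mm / a few °Cd on the group
means). Reference cohorts: control-like (535 mm, 0, 167, 231 °Cd) and
transgenic-like (743 mm, 0, 180, 246 °Cd) leaves; control-like
(10.9, 118.5 μm, 21.3, 43.4 mm) and transgenic-like
(13.2, 118.1, 29.5, 56.6) cell profiles.

What the generator does not emulate: serial correlation of measurement
error, temperature fluctuation effects (only constant-temperature logs are
fed through the thermal-time converter), the basal hyperbolic cell-length
deviation, and heteroscedastic positional scatter. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model, not robustness to those real-data features.

Recovery experiments in the test suite use 15–18 points per series
spanning sowing to just past growth cessation — the schedule a daily
protocol run to complete development produces. Noiseless refits recover
the generating parameters to 0.1 %; with 1 %-of-Lm noise the median
worst-parameter error over 200 replicate series stays under 2 %.

## Numerical choices

- Root searches: brentq with near-machine relative tolerance on brackets
  shrunk by 1e-9·(te−t0) from the domain endpoints, where the curve is
  strictly monotone by construction.
- `time_at_length(Lm)` returns `te` exactly (the plateau onset) instead of
  root-finding against a zero-slope target.
- Evaluation is fully vectorised; the exponent `(te−t0)/(te−tm)` is ≥ 1
  for valid parameters, so no fractional powers of negative numbers arise.
- Degenerate inputs: constant series → degenerate-series error; fewer than
  5 growth points or 8 profile points → input error; duplicate abscissa
  values within a leaf → the series is rejected whole (no silent
  averaging on read; explicit pooling averages coincident points).
- Batch output is written with ≥ 6 significant digits and a stable column
  order, making identical input + configuration byte-identical output.
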