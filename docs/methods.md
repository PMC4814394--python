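# Methods

`aakinetics` models the postprandial plasma appearance of amino acids
after a protein drink and scores protein quality from rat
nitrogen-balance data. This note records the models, the estimation
machinery, the numerical choices, and what the synthetic generators do
and do not emulate.

## The kinetic model

After ingestion, the stomach holds an amino-acid pool `X` that feeds the
plasma pool `Y`:

    dX/dt = -k1                X(0) = x0     (zeroth-order emptying)
    dY/dt =  k1 - k3 Y         Y(0) = y0     (while X > 0)
    dY/dt =      - k3 Y                      (after X reaches 0)

so plasma concentration rises exponentially toward the plateau `k1/k3`
until the stomach empties at `t_e = x0/k1`, then washes out first-order.
Back-flow from plasma to stomach is taken as negligible, leaving four
parameters per curve. All evaluation (curve, gradient, AUC) is in closed
form; both branches are written with non-positive exponents only so
extreme emptying times cannot overflow.

Parameters and units (units follow the data; mmol/L and minutes
expected, no conversion is ever applied):

| parameter | meaning | unit | typical magnitude |
|---|---|---|---|
| `k1` | plasma-appearance rate (zeroth order) | conc·min⁻¹ | 0.02–0.06 |
| `k3` | plasma-clearance rate (first order) | min⁻¹ | 0.006–0.015 |
| `x0` | initial stomach pool, in plasma-concentration units | conc | 3–4 |
| `y0` | fasting baseline | conc | ~2.6 |

`x0` is treated purely as a fitted parameter on the plasma-concentration
scale; the volume scaling between the stomach and plasma compartments is
deliberately left implicit.

A one-compartment first-order-absorption (Bateman) alternative is
provided for model comparison: `dX/dt = -ka X`, same clearance. Its
closed form has a removable singularity at `ka = k3`, switched to the
limit form `(y0 + x0 k t) e^{-kt}` when `|ka - k3| < 1e-8 k3`. On
plateau-shaped data this model smooths the corner and systematically
underestimates the concentration peak; `compare_models` reports AIC and
a relative peak-error diagnostic per model, which is the basis for
rejecting it.

### AUC

The area under the concentration curve is the analytic integral of the
piecewise closed form over the sampling window, split at the emptying
time. Default window 0–120 min (the trial's sampling span); the baseline
is **not** subtracted (total AUC). Both are overridable. For slow
supplements whose stomach never empties inside the window, the AUC does
not depend on `x0` at all.

## Identifiability within a 120-min window

A curve observed only on its rising branch (emptying time beyond the
window, the casein-like regime) determines `y0`, `k3` and the plateau
`k1/k3` — but `x0` only as a half-line (`x0 ≥ k1·t_max`), and `k3` only
through the curvature `e^{-k3 t}`, which at `k3·t_max < 1` is shallow.
Consequences that shape both the code and the tests:

* single-curve fits of such data can collapse onto a degenerate
  near-linear solution (`k3 → 0`, `k1` ≈ the raw slope, roughly half the
  truth); the fitters carry dedicated rising-branch starting values and
  a repair step (below) for this;
* reported `x0` for such supplements sits at the identifiability
  boundary and should not be over-interpreted;
* `k1` errors for slow supplements lie along the `k1 ∝ k3` likelihood
  ridge and remain of order 20–100 % at five subjects and 5 % assay
  noise. This is an information limit of the design, not an optimizer
  artifact: the estimator is validated to `< 1e-4` relative error on
  noise-free data, and the published 95 % interval for the casein
  appearance rate spans roughly ±35 % of its point estimate, implying a
  log-scale standard error (~0.21) at which a 25 %-accurate recovery in
  any given replicate has only ~72 % probability.

## Single-curve maximum likelihood

Additive i.i.d. Gaussian error, one variance per series. Estimation on
the transformed scale `φ = (log k1, log k3, log x0, y0)` with `y0 ≥ 0`,
by bounded least squares (scipy TRF) with the analytic model gradient.
Multi-start: a deterministic inspection heuristic (baseline sample →
`y0`; log-linear tail slope → `k3`, floored at 1e-4; `k3`·peak → `k1`;
`k1`·peak-time → `x0`; peak ties resolve to the latest time so plateaus
anchor at their end), the rising-branch start where applicable, and five
seeded log-scale jitters. Transformed parameters are bounded to
`log ∈ [-9.5, 3]` (`x0` up to `e^5`): rates below ~1e-4/min are outside
any postprandial regime and arise only from unidentified shapes.
`loglik` uses the ML variance `SSE/n`; the covariance is
`σ̂² (JᵀJ)⁻¹` at the optimum (Gauss–Newton observed information);
AIC counts five parameters.

## Population (mixed-effects) model

For subject *s*, supplement *d*: `φ_sd = β_d + b_s + c_sd` with
`b_s ~ N(0, diag(σ²_subj))`, `c_sd ~ N(0, diag(σ²_int))`, additive
Gaussian residuals with one pooled σ. Design choices:

* **Diagonal random-effect covariances** at both levels: five subjects
  cannot support a 4×4 correlation structure.
* **Pooled residual variance** across supplements (one σ per analyte).
* **Random effects on all four parameters**, log-scale for `k1, k3, x0`
  and additive (truncated at zero in the generator) for `y0`.
* A pre-ingestion sample at negative clock time is the `t = 0` baseline
  observation.
* Unbalanced designs (missing subject×supplement arms) are supported;
  the default trial design omits one arm, mirroring the study protocol.

**Estimation** alternates two steps until the variance components move
by less than 3e-5 on the log scale (cap 150 cycles): (1) a joint
penalized nonlinear least-squares update of `(β, all b, all c)` with
analytic Jacobians — residuals `(f − y)/σ` stacked with penalties `u/λ`;
(2) EM-style variance updates using the Gauss–Newton posterior
covariance of each subject's effects, `λ²_k ← mean(û²_k + V_kk)` and
`σ² ← (SSE + tr(J V Jᵀ))/n`. This is the classic alternating NLME
scheme. Candidate optima — from pooled per-supplement starts, from a
repaired start whenever a pooled fit shows a collapsed clearance rate
(`k3` below a third of the cross-supplement median; the repair borrows
the median `k3`, preserves the observed initial slope `k1 − k3 y0`, and
places the emptying time just past the window), and from one post-hoc
repair of the winner — are ranked by the Laplace-approximate marginal
log-likelihood (random-effect modes by Levenberg–Marquardt from both
warm and zero starts, Gauss–Newton Hessian in the log-determinant).
That Laplace value is the reported `loglik`.

The joint asymptotic covariance of all fixed effects — the input to the
Monte-Carlo AUC inference — is the inverse Gauss–Newton observed
information with each subject's random effects profiled out via the
Schur complement, variance components held at their estimates. Wald 95 %
intervals for rate constants are formed on the log scale. Variance
components estimated at the lower boundary (sd ≈ 1e-3) are reported as
0 and flagged. A `two_stage` method (per-curve fits, median-aggregated
per supplement with subject blocking; covariance from between-subject
scatter / n) is provided as a transparent fallback; it is noticeably
biased for slow supplements and is not the default.

## Monte-Carlo AUC inference

Per supplement: draw parameter vectors from
`N(β̂_d, Σ_dd)` on the transformed scale (positivity of rates for free;
`y0` draws floored at 0), map each through the analytic AUC, report the
empirical 2.5/97.5 percentiles. Default 50,000 draws, seeded. The point
estimate is the AUC at the fixed effects; the median of draws is
reported alongside because AUC is a nonlinear map (the two differ
slightly, and the fixed-effect point can in principle fall outside its
own interval — flagged, never silently). Pairwise comparisons draw the
two supplements independently (block-diagonal covariance, the stated
independence assumption) and report
`p = 2·min(P(diff ≤ 0), P(diff ≥ 0))` clipped to `[2/n_draws, 1]`,
unadjusted for multiplicity. A non-PSD covariance block raises an error
naming the supplement; eigenvalues within −1e-10 of zero are treated as
exact zeros, which makes the zero-covariance degenerate case exact.

## Protein-quality metrics

With period totals (mg N) and the correction constants
`N_metabolic = 1.01 mg N/g DM` (scaled by dry matter actually consumed)
and `N_endogenous = 15.2 mg N/day`:

    TD = (N_in − (N_fae − N_met)) / N_in × 100
    BV = (N_in − (N_fae − N_met) − (N_ur − N_end)) / (N_in − (N_fae − N_met)) × 100

Both are returned uncapped, with a warning outside [0, 100]. Protein is
nitrogen × 6.38 (milk factor). Metrics are computed per animal and
summarized as mean ± SEM per diet (full precision; rounding is left to
presentation).

PDCAAS: per scoring category (His, Ile, Leu, Lys, Met+Cys, Phe+Tyr, Thr,
Trp, Val; sulphur and aromatic pairs pooled by summation),
`score = AA_product / AA_reference × TD`; the overall score is the
limiting (minimum) category capped at 100 by FAO convention, with all
uncapped scores reported. Reference patterns are configuration data
shipped as named presets — the default is the FAO/WHO 2007/2011 pattern
for 3–10-year-old children (His 15, Ile 30, Leu 61, Lys 48, Met+Cys 23,
Phe+Tyr 41, Thr 25, Trp 6.6, Val 40 mg/g protein) — never constants
inside the scoring math. The published per-category score tables cannot
be inverted to a single consistent reference pattern (the implied
histidine requirement varies by row), so exact reproduction of those
tables is out of reach by construction; the scientifically meaningful
property — every category of every product clears 100 before capping —
is what the tests assert.

## Synthetic generators

`simulate_trial` emulates the crossover: 5 subjects × 4 supplements on
the grid 0, 10, 20, 30, 45, 60, 90, 120 min, log-normal random effects
at subject and subject×supplement level (default sd 0.2 each — the
canonical ~20 % between-subject kinetic variability), additive Gaussian
noise truncated at zero (default sd = 5 % of each noise-free curve's
maximum; an absolute mode exists), and the default exclusion of one
subject×supplement arm. True `k1` per supplement uses the published TAA
point estimates (0.0585 / 0.0594 / 0.0560 / 0.0194); `k3`, `x0`, `y0`
were never published and are plausible fills (baseline 2.6, whey plateau
≈ 4.4 reached while the stomach empties over ~1 h, casein emptying time
≈ 200 min) clearly labelled non-study values. Generated curves therefore
have the published rate structure but roughly 25 % lower AUCs than the
published tables — the generator validates the machinery, not the
absolute AUC scale.

`simulate_balance` inverts the TD/BV equations at target values
(defaults: the published 97/97/94/96 and 58/78/87/69) under the study
ration (10 g DM, 150 mg N per day, 5 days) to noise-free faecal and
urinary nitrogen, then adds Gaussian measurement noise (defaults 8 and
20 mg N per period, chosen once to give group SEMs of the published
magnitude at five animals) and floors at zero.

What the generators do **not** emulate: assay heteroscedasticity,
within-day autocorrelation, inter-occasion variability, non-normal
effect distributions, or any physiological feedback (insulin-driven
clearance changes). Passing recovery tests therefore shows the pipeline
is correct under its own assumptions, not that real data satisfy them.

## Numerical conventions

* Every stochastic step takes an explicit integer seed; identical seeds
  give byte-identical outputs (CSV floats written as `%.17g`, read back
  with round-trip precision).
* Degenerate inputs fail loudly: constant series, empty windows, zero
  intake, missing scoring categories, duplicate arms, < 2 subjects.
* Tie-break: a flat concentration maximum is assigned to its latest
  time point (plateau end).
* Residuals and Jacobians inside the mixed-effects machinery are capped
  at 1e8 so extreme random-effect excursions cannot overflow.

## Problem sizes used by the test suite

Oracle agreement runs 10⁴ random parameter draws against vectorized RK4
(1500 steps per branch segment) and 10³ draws against a 0.001-min
trapezoid; interval calibration uses 200 estimator replicates at 2,000
draws each; recovery studies use the 5×4 study design over 10 seeds; the
null-uniformity check uses 500 replicates at 1,000 draws. These sizes
keep the full suite around two minutes while leaving each check's
statistical resolution well below the asserted tolerances.

## Known limitations

* `x0` (hence emptying time) is reported at an identifiability boundary
  for supplements that never empty within the window.
* The fixed-effect covariance ignores variance-component uncertainty
  (standard Wald practice; anti-conservative at n = 5).
* The two-stage fallback is biased for slow supplements; it exists for
  transparency and speed, not as the estimator of record.
* Pairwise AUC p-values are unadjusted for multiplicity, matching the
  analysis this package mirrors.
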