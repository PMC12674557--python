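# Methods

This note documents the model, its conventions and the judgement calls made
where a published economic evaluation leaves the machinery unstated.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Time, cycles, discounting

Time is measured in months (1 month = 30.4375 days) throughout; the printed
Weibull/log-normal survival parameters reproduce the source trials' medians
(≈15.6 months OS, ≈6.7 months PFS) only on that scale.  The cohort model
advances in 3-week cycles (21/30.4375 ≈ 0.690 months).  Costs and effects
are discounted at 3% per year with the per-cycle factor (1.03)^(−t/12).

**Accrual convention.**  State membership is counted at the end of each
cycle: a quantity accrued over cycle *k* is weighted by occupancy and
discount factor at time *k·u*.  No half-cycle correction is applied by
default; `ModelSettings(half_cycle_correction=True)` switches to the
trapezoid (average of start- and end-of-cycle sums), which is also what the
closed-form life-expectancy checks in the test suite use when comparing
against ∫S dt.  End-of-cycle counting was adopted because it reproduces the
published base-case life-years under the printed survival parameters;
start-of-cycle counting overshoots both arms by roughly half a cycle.

**Horizon.**  The model stops at the first cycle where cohort mortality
exceeds 0.999, capped at 40 years.  With the base-case curves the stop rule
binds at roughly 7 years (≈119 cycles) for the comparator arm and ≈9.4
years for the intervention arm; extending the cap changes life-years by
well under 0.1% (tested).

## State occupancy and transitions

Occupancy comes directly from the survival curves (partitioned-survival
identity): PFS(t) = S_PFS(t), Death(t) = 1 − S_OS(t), PD(t) = S_OS(t) −
S_PFS(t), clamped at zero.  The extrapolated log-normal PFS tail eventually
crosses the Weibull OS curve (by ≤ 0.006 in the base case); the engine
clamps PFS occupancy to OS and warns.  Per-cycle transition probabilities
(PFS exit, PFS→Death, PD→Death) are derived as diagnostics that replay to
exactly the same occupancies; deaths are attributed to PFS and PD in
proportion to occupancy, clamped so PD inflow stays non-negative.  They are
not used for accrual.

The intervention arm applies hazard ratios on the cumulative hazard,
S_adj(t) = S(t)^HR, for both endpoints — including the log-normal PFS
baseline, which is not closed under proportional hazards; this is the
standard economic-modelling reading of a single hazard ratio applied to a
fitted baseline curve.

## Outcomes and costs

QALYs weight PFS occupancy by 0.76 and PD occupancy by 0.68.  The grade ≥3
adverse-event disutility (0.16, weighted by the arm's summed AE incidence)
is charged once at model entry for one cycle's duration; applying it
per-cycle instead would shift QALYs by < 0.01.  Death carries utility 0 and
cost 0.

Costs per cycle: drug acquisition (linear mg pricing, no vial rounding;
bevacizumab dosed at 15 mg/kg × 70 kg) and disease monitoring are charged
against PFS occupancy (treat-to-progression); adverse-event management is
charged once in the first cycle; post-progression care is the
`p_subsequent_active`-weighted mix of subsequent active treatment and best
supportive care.

**Post-progression accrual.**  The published input table prices subsequent
treatment "per patient", but charging it once at progression yields total
costs roughly a third of the published totals, while charging the expected
mix against PD occupancy every cycle approximately reproduces them.  Both
modes are implemented (`post_progression_cost_mode`); `per_cycle` is the
default.  Total costs are therefore convention-dependent and are treated as
soft (±15%) rather than exact targets; the incremental *sign* is stable
across conventions.

A consequence worth flagging: under per-cycle charging, parameters that
lengthen time in PD (notably the PFS hazard ratio) move total costs more
than under one-time charging, so in the one-way analysis the PFS hazard
ratio's ICER swing slightly exceeds the OS hazard ratio's.  Both hazard
ratios dominate the tornado by a wide margin, with the PD utility the
widest remaining bar — the qualitative ranking reported for this model.

## Survival fitting and model selection

Maximum likelihood under right censoring (density for events, survival for
censored subjects), optimized on log-transformed positive parameters
(Nelder–Mead, five deterministic restarts, 1e-10 tolerance on the
log-likelihood).  The exponential rate uses its closed form, events/total
time.  Families are compared by AIC with exact ties broken in the order
exponential < Weibull < log-normal < log-logistic (parsimony first).  The
fitted Weibull agrees with an independent implementation (lifelines) to
about six significant figures in the tests.

## Indirect comparison

The Bucher contrast is computed analytically: with two trials and a
fixed-effects normal model on the log scale, the network estimate is the
difference of log hazard ratios with summed variances, so no MCMC is
needed and results are exactly reproducible.  Standard errors come from CI
widths under log-normality, se = (ln hi − ln lo)/(2·1.959964).  The printed
trial summaries 0.58 (0.42–0.79) and 0.90 (0.69–1.18) give an OS contrast
of 0.64 at two decimals.  For PFS the analytic contrast of 0.59/0.63 is
≈ 0.94, whereas the published model input is 0.95 — consistent with MCMC
sampling noise in the original analysis.  The package does not force the
match: the indirect-comparison module reports 0.94, and the cohort model's
default configuration uses the published 0.95 as its input.

## Sensitivity analyses

A published (low, high) range is read as a 95% interval, se = (high −
low)/3.919928.  Beta and gamma distributions are matched to (mean, se) by
method of moments; hazard ratios sample log-normally with median at the
point estimate.  The discount rate, when varied, uses a beta rescaled to
[0, 0.05]; it is held fixed in the PSA by default (varying it there is
unconventional) but participates in the one-way analysis.  The baseline
survival parameters carry no published uncertainty and are held fixed in
the PSA.  Parameters are sampled independently (no correlation structure is
published); both arms are evaluated on the same draw, so shared parameters
(utilities, unit costs, baseline curves) are common to both.  CEAC ties in
net monetary benefit are split equally; the crossover willingness-to-pay is
linearly interpolated on the grid (default $0–2M in $10k steps), so with
degenerate distributions it equals the deterministic ICER to within half a
grid step.

## Synthetic-data generator

`synthetic_trial` emulates a COSMIC-312-like arm: n ≈ 250–300 subjects,
event times from the fitted Weibull (OS) or log-normal (PFS), uniform
accrual over ~20–23 months and a fixed administrative cutoff, giving
trial-like right censoring (roughly 15–35% depending on design).
Digitization is emulated by sampling the KM step function on a regular grid
(default 1 month) and adding truncated Gaussian error (default sd 0.005
absolute survival units), followed by monotone repair.  It does **not**
simulate covariates, treatment switching, informative censoring or
per-subject costs — so passing round-trip tests demonstrate fidelity of the
reconstruction machinery under administrative censoring, not robustness to
those real-data features.

**Fidelity windows.**  Round-trip tests digitize the curve over 0–30
months, the window in which a meaningful number of subjects remain at risk
(published figures are likewise plotted only over that range).  Beyond it,
1–3 subjects remain and a single event moves the KM estimate by more than
0.05, so no reconstruction can track the curve to 0.02 there.

## Reconstruction conventions

With a fixed-grid digitizer the survival value sampled *at* a risk-table
time already includes all events up to that time, so intervals are defined
as (T, T_next] and the published at-risk count is matched after the events
of the boundary click.  Censorings are spread uniformly within the
interval; event counts at each click follow the product-limit identity
against the running reconstructed KM level, rounded half-up with a carried
remainder clamped to ±0.5 events (clamping matters when digitization error
pushes a click above the running KM level).  After the fixed-point
adjustment of the censoring count, a local search (±15) keeps the count
that matches the published at-risk target while minimizing the KM tracking
error — without it, event/censoring attribution drifts in the
small-numbers tail.  When no event total is published (the usual case) the
final interval is reconstructed without the event-total adjustment;
`total_events` enables it.

## Known limitations

- Total costs (and therefore the PSA percentages and the crossover WTP)
  depend on the unstated post-progression accrual convention; they are
  reproduced to ±15%, not exactly.
- The proportional-hazards adjustment of a log-normal baseline is a
  modelling convention, not a statistical model of the underlying trials.
- Extrapolation beyond trial follow-up inherits all the usual caveats of
  parametric tails fitted to ~30 months of data.
- The generator's administrative-censoring model does not produce the
  mid-study dropout patterns of real trials; reconstruction accuracy on
  real digitized figures will also depend on digitization quality.
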