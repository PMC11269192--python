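# Methods

## Model

The package implements a three-state partitioned survival model (PSM) for
two treatment strategies in anthracycline- and taxane-refractory metastatic
breast cancer: utidelone (30 mg/m² IV, days 1–5) plus capecitabine
(1,000 mg/m² orally twice daily, days 1–14) versus capecitabine alone
(1,250 mg/m², same schedule), in 21-day cycles over a 5-year horizon.

State occupancy is read directly off the arm-level survival curves rather
than from transition probabilities:

- progression-free: `pf(t) = S_PFS(t)`
- dead: `dead(t) = 1 − S_OS(t)`
- progressed: `pd(t) = S_OS(t) − S_PFS(t)`, clamped at 0 where the
  independently fitted curves cross (a warning is issued if clamping affects
  more than 5% of cycles).

The base-case curves are the published fits from the registration trial
(NCT02253459): log-logistic OS, `S(t) = 1/(1 + (t/λ)^γ)` with λ the median
(combination λ=15.224, γ=2.826; monotherapy λ=12.534, γ=2.933), and Weibull
PFS with a rate-like scale, `S(t) = exp(−λ t^γ)` (combination λ=0.0345,
γ=1.51337; monotherapy λ=0.072, γ=1.3696), time in months. These
parameterizations are the only ones under which the published scales are
consistent with the published model medians.

## Time conventions

One cycle is 21 days; the default day-to-month conversion is 30 days/month,
making a cycle exactly 0.7 months. This choice (configurable via
`CycleGrid(days_per_month=...)`) is deliberate: on a 0.7-month grid the
model medians implied by the base-case curves fall exactly on the published
values (combination PFS 11 cycles = 7.7 months, combination OS 22 cycles =
15.4, monotherapy OS 18 cycles = 12.6), whereas a 30.4375-day month gives
7.59/15.87/13.11. Grid medians are reported as the first cycle-start time at
which the relevant survival is at or below 0.5.

State membership is evaluated at cycle start; per-cycle person-time is
membership × cycle length (a left Riemann sum) with the final partial cycle
truncated at exactly 5 years, and no half-cycle correction by default. The
left sum of a decreasing survival curve overstates person-time by roughly
half a cycle, which for the base-case arms is a 1.8–2.2% upward bias
relative to a 1-day grid; the exact discount-0 identity
`acquisition = per-cycle cost × Σ pf(k)` holds only under this convention,
which is why it is the default.

Discounting is `1/(1+r)^(t/12)` with t in months, r = 5%/year for both costs
and health outcomes (sensitivity range 0–8%).

## Costing

Six discounted categories per arm, in 2023 USD (converted at 7.238 RMB/USD;
the rate is provenance metadata only — all computation is in USD). Doses use
a reference body surface area of 1.73 m².

- **Acquisition.** Drug quantities are rounded to dispensable units with
  surplus discarded. Defaults: utidelone rounded to the nearest 50 mg vial
  per day (51.9 mg/day → 1 vial/day × 5 days = US$2,044.70/cycle);
  capecitabine rounded to the nearest 500 mg tablet per administration, with
  tablets grouped into packs of 12 at US$36.51, packs rounded up per cycle
  (combination: 84 tablets = 7 packs; monotherapy: 112 tablets = 10 packs).
  A literal per-500-mg price cannot reproduce the published acquisition
  totals; the pack convention reproduces them within ~1–3%. All of this is
  configuration (`PackSpec`), not hard-coded.
- **Administration.** On each of the 5 intravenous days the combination arm
  incurs hospitalization, infusion, and one unit each of the premedication
  set (cimetidine, diphenhydramine, dexamethasone): US$27.97/day. The
  oral-only arm has zero administration cost.
- **Monitoring.** A laboratory panel (ECG, hematology, serum chemistry,
  urinalysis: US$36.19) every cycle and contrast CT (US$296.96) every second
  cycle, scheduled at cycles 1, 3, 5, …; this schedule reproduces the
  published monitoring totals within ~3%.
- **Treatment until progression.** Acquisition, administration and
  monitoring all accrue in proportion to progression-free occupancy.
- **Adverse events.** Grade ≥3 events are costed once, in the first cycle.
  The mechanistic value Σ incidence × unit cost (≈US$232 for the
  combination) does not reproduce the published category total (US$855.63),
  so the category accepts an override; the shipped defaults carry the
  published totals (855.63/477.81) and the mechanistic value is always
  reported alongside (`CostBreakdown.mechanistic_ae`).
- **Progressed-state management.** Either a configurable per-cycle
  consultation rate × progressed occupancy, or an override total; the
  published totals (496.50/439.50) ship as defaults since no unit cost for
  the progression consultation is published.
- **Terminal care.** US$1,036.15 weighted by the per-cycle death increment.

## Outcomes

Utilities 0.85 (progression-free), 0.69 (progressed), 0 (dead). Grade ≥3
adverse events subtract utility once, at time zero, as
`(−0.28) × (summed incidence) × one cycle's duration` (≈0.005 QALY); the
magnitude and interpretation are configurable. Outcomes are discounted like
costs.

## Sensitivity analysis

**One-way DSA.** Every parameter moves to its published bounds (which are
±20% of base), the discount rate spans 0–8%, and survival-curve scales move
±20% (no bounds are published for the curves); the base case is restored
between rows and rows are ranked by ICER span. With the adverse-event and
progressed-management categories in override mode, the underlying AE unit
costs have zero one-way influence by construction.

**PSA.** 10,000 joint redraws: gamma for costs (including the two override
category totals), beta for incidences, utilities and the discount rate, the
disutility sampled on its magnitude and negated. Moments are matched so the
mean equals the base value and SD = (upper − lower)/(2·1.96), reading the
published range as a 95% interval. Survival curves stay at base values (no
sampling bounds exist for them). Because progressed and progression-free
utilities are drawn independently, a draw can invert their ordering; the
progressed utility is capped at the progression-free value in that case.
Each parameter has its own child stream of the master seed (seed plus a CRC
of the parameter name), so adding a parameter never reshuffles the others
and runs are exactly reproducible.

## Subgroups

For a subgroup with OS hazard ratio `hr`, the treated arm's OS is
`S_comparator(t)^hr` under proportional hazards, applied to the
overall-cohort comparator curve; PFS curves and all cost inputs stay at
overall-cohort values. This makes the subgroup ICER a deterministic,
strictly increasing function of `hr`, so equal published HRs map to equal
ICERs. The subgroup cost-effectiveness probability additionally draws `hr`
log-normally (median = published HR, 95% CI = published CI) inside the PSA
and reports the fraction of draws with positive net monetary benefit at the
WTP threshold of US$35,519.39/QALY (three times GDP per capita). A
degenerate CI falls back to the fixed HR. Note the deliberate asymmetry: the
subgroup engine re-derives the treated arm from the comparator curve, so
`hr` equal to the overall-cohort hazard ratio does not reproduce the base
case.

## Synthetic trial generator

`simulate_ipd` emulates the trial structure the analysis assumes: 2:1
allocation (default 300/150 — the published ratio with a configurable
total), per-subject OS drawn from the arm's OS curve by inverse transform,
observable PFS = min(progression draw, OS time), uniform accrual over 12
months, and administrative censoring at a 60-month cutoff. The min()
coupling is the only dependence imposed (no joint model is published), and
it means the observable PFS law is `S_PFS·S_OS`, not the marginal PFS curve
— recovery tests therefore target the coupled law's median. `km_digitize`
samples the product-limit estimate on a grid with a number-at-risk row and
optional Gaussian jitter; `reconstruct_ipd` inverts it with the standard
interval-balancing pseudo-IPD algorithm. What the generator does not
emulate: digitization bias beyond jitter, informative censoring, dropout,
and individual-level cost or adverse-event heterogeneity (the economic model
is cohort-level).

## Numerical choices

- Parametric MLE under right censoring: Nelder-Mead on log-parameters with
  tolerance 1e-8 and moment-based multi-starts per family; densities and
  quantiles from `scipy.stats`. Model selection minimizes AIC, ties broken
  by BIC, then by the conventional family order.
- Reconstruction allocates whole events via the product-limit relation and
  tunes within-interval censorings until the at-risk count matches the next
  anchor; a shortfall larger than max(2, 20% of those at risk) raises an
  error naming the interval, smaller ones are treated as rounding drift.
- Monetary values are rounded to cents only at serialization.

## Known limitations and discrepancies

- The published base-case QALYs (1.54/1.05) exceed what the published
  curves can support over a 5-year horizon under any accrual convention we
  evaluated (the restricted mean OS of the monotherapy curve is ~15 months,
  bounding its QALYs below ~0.97 even undiscounted); the pipeline's
  mechanistic values are ≈1.12/0.93, so its incremental QALY (≈0.19) and
  base ICER (≈US$142,000/QALY) sit on a different scale from the published
  0.49 and US$53,874. Quantities defined relative to the model's own ICER
  (the PSA probability at that threshold) reproduce the published ~49%.
- The published subgroup ICERs follow ICER(hr) ≈ ΔC/(1.44·(1/hr − 1)),
  the signature of an unbounded exponential-mean extrapolation, which a
  5-year partitioned survival model cannot produce; this package's subgroup
  ICERs preserve the published ordering and equal-HR structure but not the
  published magnitudes at low HRs.
- The left-Riemann accrual bias (~2%) is visible when comparing against a
  1-day grid; enable `CycleGrid(cycle_length_days=1)` for near-continuous
  accrual if the exact discrete identities are not needed.
- Grade 1–2 adverse events, rare grade 3–4 events, dose reductions and
  societal costs are out of scope, as in the source analysis.
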