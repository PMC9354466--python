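# Methods

This note documents the model implemented by `nsclc_cea`: its structure,
the numerical choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Decision problem

Two first-line strategies for locally advanced or metastatic nonsquamous
NSCLC without EGFR/ALK driver alterations are compared from the Chinese
healthcare-system perspective: tislelizumab plus pemetrexed–platinum (TPP)
versus pemetrexed–platinum alone (PP). Outcomes are lifetime discounted
costs (2021 USD) and QALYs; the decision rule is ICER < WTP with
WTP = $35,663/QALY (3× 2021 per-capita GDP). Both costs and effects are
discounted at 5% per year.

## Survival inputs

**IPD reconstruction.** Published KM curves are digitized as (time,
survival) coordinates on a uniform grid plus a number-at-risk table. The
reconstruction solver works interval by interval: within each risk-table
interval a censoring count is iterated (censor times spread uniformly)
until the implied number at risk at the next boundary matches the table;
at each curve coordinate the event count is the integer that moves the
running product-limit estimate closest to the digitized value (ties round
to fewer events, so output is deterministic). Event times are placed at
the *midpoint* of their grid cell: a drop first seen at coordinate `t_k`
only localizes events to `(t_{k-1}, t_k]`, and right-edge placement would
delay every event by half a cell — at small `t` this masquerades as an
increasing hazard, inflates the fitted Weibull shape by about +0.05, and
biases the recovered median upward. Midpoint placement removes this bias
while leaving the reconstructed KM estimator unchanged at every grid
coordinate. Small disagreements between a noisy curve and the risk table
(a few subjects) are carried forward with a warning; gross inconsistencies
(more than max(2, 10% of the cohort)) raise an error. Without a risk
table the solver assumes no censoring before the last coordinate and warns.

**Parametric fitting.** Candidates are exponential, Weibull, log-logistic,
log-normal and Gompertz, fitted by maximum likelihood under right
censoring (lifelines; the exponential uses its closed form events/total
time; the Gompertz shape is constrained positive so survival always decays
to zero — a negative shape would imply an immortal fraction, which is
incompatible with this disease). Selection is by minimum AIC, ties broken
toward fewer parameters and then alphabetically. BIC is reported alongside.

**Arm effects.** The control (PP) arm is fitted; the intervention (TPP)
arm is derived by proportional hazards, `S_TPP(t) = S_PP(t)^HR`, separately
for PFS (HR 0.645) and OS. Subgroups swap in their own PFS hazard ratio
and reuse the population OS hazard ratio (subgroup OS data were not
published). Direct fitting of a second arm's reconstruction is available
through the same API but the HR route is the primary path.

## Markov model

States: PFS on treatment, PFS off treatment after adverse-event (AE)
discontinuation, progressive disease (PD), death; 21-day cycles over 20
years → ceil(20·365.25/21) = 348 cycles; the cohort starts 100% in PFS on
treatment. Unit conversions use 1 month = 30.4375 days throughout.

Per cycle starting at time `t` with length `Δ`:

* every alive state's death probability is the OS interval probability
  `q_os = 1 − S_os(t+Δ)/S_os(t)`, so modelled all-cause survival equals the
  OS input at every cycle boundary by construction (this is the resolution
  of the open competing-risks question: death claims its OS-implied share
  first);
* progression takes the remainder of the PFS exit probability,
  `p_pd = max(0, q_pfs − q_os)`, floored at zero if the curves cross;
* of the surviving, non-progressing on-treatment mass, a constant
  per-cycle fraction `ae_disc` moves to the off-treatment PFS state
  (calibrated from a cumulative discontinuation proportion via
  `1 − (1−cum)^(1/n)`); once off treatment, never back on.

The off-treatment PFS state shares PFS transitions and utility with the
on-treatment state; only drug-acquisition costs stop. Consequently total
PFS occupancy is invariant to `ae_disc` and the model collapses exactly to
the three-state model when `ae_disc = 0` (both are tested invariants).

When sensitivity analyses vary the OS hazard ratio upward, the derived OS
curve can fall below the PFS curve; there the PFS curve is clipped to OS
(death claims all exits). For fitted base inputs a crossing beyond 1e-6 is
treated as an input error instead.

**Half-cycle correction** is on by default: state-occupancy rewards are
valued at cycle midpoints (mean of adjacent occupancy rows). One-off
rewards (first-cycle AE burden, end-of-life cost on death entrants) are not
half-cycle corrected. Discounting uses the factor at each cycle's start,
`(1+r)^(−k·Δ/365.25)`.

## Economics

Costs per cycle: drug acquisition only in PFS-on-treatment (per-m² dosing
with BSA 1.72 m², Calvert-formula carboplatin with CrCl 70 ml/min, doses
rounded up to whole vials by default — exact-milligram billing is a config
switch; per-drug maximum cycle counts cap induction drugs), premedication,
follow-up and best supportive care for all alive states, subsequent
anticancer therapy for PD occupancy scaled by the proportion treated (50%
in both arms by default, separately variable per arm), and a one-time
end-of-life cost on entry into death. AE treatment costs and disutilities
are frequency-weighted sums over the per-arm AE tables, charged once in
the first cycle — the weighted-sum formulation is trace-independent, so
amortizing it would only re-distribute the same discounted total.

QALYs: utility 0.856 for both PFS states and 0.768 for PD, scaled by cycle
length in years, minus the one-off AE disutility.

ICER handling: when the intervention is cheaper and more effective it
dominates (cost-effective at any WTP) and no ICER is reported; dominated is
the mirror case; ΔE = 0 falls back to cost comparison with an undefined
ICER flag.

## Sensitivity analysis

* **One-way DSA**: each parameter in the flat registry (hazard ratios,
  utilities, per-drug prices, AE burdens, care costs, subsequent-therapy
  proportions, AE discontinuation) is pushed to its low/high bound with
  everything else at base. Default ranges are ±20%; hazard ratios use
  their 95% CIs. Entries are sorted by descending ICER span (tornado
  order); dominance at an endpoint is mapped to a signed infinity.
* **Threshold analysis**: the ICER is not monotone over wide brackets — it
  diverges where ΔE crosses zero — so the search first scans the bracket
  on a 33-point grid, locates the first finite sign change of ICER − WTP,
  and bisects inside it to a relative tolerance of 1e-4. Absent a crossing
  the analysis reports "no crossing" and the run continues.
* **PSA**: beta distributions for utilities and probabilities, gamma for
  costs, lognormal for hazard ratios (uniform available), hyperparameters
  by method of moments from (base, low, high) with the range read as a 95%
  interval; parameters are sampled jointly and independently — no
  correlation structure, a documented limitation. One master seed spawns a
  substream per iteration, so results are reproducible and iteration counts
  can change without reshuffling earlier draws. Invalid draws are
  resampled (>100 rejections aborts with a distribution-specification
  error). The CEAC reports, per WTP value, the fraction of draws with
  positive net monetary benefit.

## Synthetic-data generator

The generator emulates: parametric PFS/OS ground truth per arm (arm
effects as hazard ratios applied on the hazard scale, exact for the
closed families exponential/Weibull/Gompertz), administrative censoring at
a follow-up horizon, exponential dropout, uniform-grid digitization with
truncated-Gaussian probability noise (sd 0.005 by default) re-monotonized
by cumulative minimum, and risk tables counting subjects under observation.

Joint PFS/OS dependence is comonotone: one uniform per subject is mapped
through both inverse survival functions. This preserves both specified
marginals exactly (an additive PFS + post-progression construction would
not) and guarantees PFS ≤ OS whenever OS stochastically dominates PFS;
residual violations are clamped. Perfect rank correlation is not
realistic at the patient level, but the cohort model consumes only the
marginals, so no downstream quantity is affected.

Not emulated: patient covariates (subgroups exist only as hazard ratios),
informative censoring, accrual patterns, interval-censored progression
assessment schedules, and digitization reading errors on the time axis.
A green end-to-end test therefore establishes that the pipeline recovers
a world of this simplified shape — not that the published trial's exact
curves would be recovered.

The reference scenario fixes the trial-anchored values (median PFS 7.6
months, PFS HR 0.645, utilities, prices and thresholds listed in the
README) and declares placeholders for everything in the unavailable
supplement; the control-arm OS median (18 months) and the OS HR (0.70) are
placeholders at magnitudes typical of chemotherapy-only nsqNSCLC cohorts.

## Statistical note on round-trip recovery tests

The median of an exponential MLE at n = 500 (≈485 events) has a
Monte-Carlo standard error of roughly 1/√events ≈ 4.5%, so a single
simulated cohort misses a 5% recovery tolerance about a third of the time
for *any* correct pipeline. The end-to-end recovery test therefore takes
the median over five independent replicates: draw luck cancels, pipeline
bias (the quantity of interest) does not.

## Known limitations

* Proportional hazards is assumed exactly and indefinitely for the
  extrapolated intervention arm; no time-varying or waning effect.
* PSA parameters are independent; utilities, costs and hazard ratios are
  in reality correlated.
* Subsequent-therapy cost is a constant per-cycle PD cost; a one-time
  alternative exists but treatment-line structure is not modelled.
* The AE discontinuation probability is constant per cycle, calibrated
  from a single cumulative proportion.
* Reference prices/AE tables are placeholders; conclusions from the
  packaged configuration are about the synthetic scenario, not the
  published cohort.
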