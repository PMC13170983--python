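# Methods

This note documents the model, the packaged default inputs and the synthetic
data generator: what each assumes, where the defaults come from, and what the
passing tests do and do not establish.

## 1. Cohort model

A closed cohort enters at age 54 (59% women) and is tracked in annual cycles
over three states: type 2 diabetes, remission from diabetes, and death.
Occupancy is evaluated at cycle start with no half-cycle correction; annual
accounting then reproduces the reference tables' arithmetic exactly, and the
engine is verified against an independent per-cycle loop oracle in the tests.

- **Remission assignment.** The arm-level remission schedule *S(t)* is applied
  to survivors each cycle (remission cannot outlive the cohort), keeping
  occupancies conserved to 1e-12 per cycle. Remission is anchored at the
  12-month assessment and absorbing on relapse; re-remissions are not
  modelled.
- **Mortality.** Age- and sex-specific annual death probabilities by diabetes
  status; the remission state uses the non-diabetes rates. The cohort is run
  with sex-blended rates (0.59 × female + 0.41 × male), a cohort-level
  approximation that avoids splitting the trace by sex; at these rates the
  approximation error on life expectancy is far below the calibration
  tolerance.
- **Horizons.** `five_year` truncates at 5 cycles. `lifetime` runs until the
  alive fraction falls below 1e-6 or age 110, whichever comes first.
- **Discounting.** 3.5 %/yr for costs and QALYs, first year undiscounted
  (factor (1+r)^-(t-1)). The convention is a config switch
  (`first_year_undiscounted`) because practice varies.

## 2. Remission estimation

Annual remission statuses for 12-month remitters are classified with explicit
missing-record rules: a missing year is deemed the relapse year when the next
available record shows relapse; otherwise the participant is censored at the
first year with no further record. The arm-level curve is the observed
12-month remission proportion times the product-limit maintenance estimate
(via `lifelines`).

**Risk-set timing.** Relapses recorded at a visit are processed before
end-of-follow-up censorings at the same visit. Censorings *at a missing
record*, however, leave the risk set half a cycle early: such a participant's
information truly ends at the previous assessment, and keeping them in the
risk set of a visit at which their relapse could never be observed biases the
survivor function upward (≈ +0.008 on S(5) at n = 149 with 2 %/yr dropout).
The worked product-limit example in the test suite pins this behaviour.

**Extrapolation.** Beyond year 5 the curve declines at the geometric mean
rate observed between years 1 and 5, r = (S(5)/S(1))^(1/4) ≈ 0.678, and is
exactly zero beyond a 10-year cap. No adjustment is made for extended
support, whose receipt was not associated with better maintenance.

## 3. Costs

All costs are GBP at 2020/21 prices. Annual healthcare costs per participant
are carried in five categories (primary care, other, secondary care,
hospital, medicines); medicines are carried as an annual cost rather than
dose-level records, and hospital use as an annual cost rather than
episode-level records (a per-episode helper implementing tariff base +
excess bed-days beyond the trim point is provided for unit-costed inputs).

- **KM sampling average.** The mean annual cost per arm-year is taken over
  participants still under observation in that year and applied to the
  modelled proportion alive. With no censoring this is exactly the
  complete-case mean (tested).
- **Intervention costs.** Set-up (£68 flat, year 1) + sachets × £1.50 +
  visits × 25 minutes × £0.7526/minute, intervention arm, years 1–5 only.
  The sachet price and per-minute rate are calibration defaults (§6).
- **Beyond year 5.** Both arms cost the control arm's year-5 non-remission
  mean; participants in remission cost a fraction (1 − s) of it, with
  s = 0.73 the average proportional saving for remission over years 2–5 (§6).

## 4. Utility

A marginal linear GEE (exchangeable within-subject correlation, robust SEs)
regresses EQ-5D-3L index values on time-varying remission status; the default
effect is +0.037 (SE 0.0154). Baseline covariates can be included but none
were predictive in the reference analysis, so the packaged model is
status-only. State utilities are UK population norms by age band and sex with
relative decrements: the diabetes decrement compares the regression's
predicted non-remission utility at baseline age/sex (0.7648 packaged) with
the matched norm; the remission decrement adds the effect to that prediction.
The absolute remission benefit therefore shrinks proportionally as norms
decline with age. The packaged norm table is an editable synthetic default
with a realistic age gradient; each row carries a source label.

## 5. Uncertainty

The PSA combines, per iteration: a nonparametric bootstrap of participants
(stratified by arm, original arm sizes) with full re-estimation of remission
curves, KM sampling-average costs, the remission saving fraction and
intervention costs; a normal draw of the utility effect around the fitted
coefficient; and beta draws (method of moments, 10% relative SE by default)
applied as multiplicative factors to each mortality table, with the
remission-state rate clipped never to exceed the diabetes rate. The GEE is
not refit per resample — the utility effect enters through its sampling
distribution, mirroring a two-stage analysis. Percentile intervals use the
empirical (lower/higher) method so a 2-draw interval is exactly (min, max).
The CEAC reports, per willingness-to-pay value on a £0–£50,000 grid (£1,000
steps), the fraction of draws with positive net monetary benefit.

Scenario analyses modify inputs structurally: scaling the mortality advantage
of remission (interpolating the remission-state rate between the non-diabetes
and diabetes tables), scaling the utility effect, halving the entire
remission schedule (years 1 and 2 included), switching costing to
arm-by-remission-status cells, and truncating the horizon to 5 years. All
scenarios in a batch share one seed, so differences between rows are
attributable to the modification alone; QoL-only scenarios leave cost columns
bit-identical (tested).

## 6. Calibrated packaged defaults

Source-level inputs (unit prices, mortality rates, year-3/4 remission
proportions, annual cost profiles) are not published; the packaged values are
calibration choices solved once, by one-dimensional root finding per knob in
an alternating loop, against the reference arm-level results:

| knob | default | solved against |
|---|---|---|
| Gompertz level (women, age 54) | q_nd = 0.002239 | control life expectancy 23.48 y |
| Gompertz slope / sex ratio | 0.122 / 1.60 | fixed shape choices (realistic steepness) |
| diabetes mortality ratio | 1.7703 | lifetime incremental QALYs 0.080 |
| cost profiles (per arm-year) | control 1414→2071, intervention 1114→1405 | discounted 5-yr healthcare totals 7928 / 5837 |
| practitioner cost per minute | 0.7526 | discounted intervention total 1691 |
| baseline predicted utility | 0.7648 | control 5-yr QALYs 3.37 |
| remission saving fraction s | 0.73 | lifetime incremental cost −496 |

Two open choices deserve note:

- **Years 3–4 remission.** Only the year-1/2/5 anchors (0.46, 0.36, 0.097)
  are reported; the package interpolates linearly (0.2723, 0.1847). This
  yields 1.37 modelled remission-years over 5 years, slightly below the
  reference 1.42 (which implies interior values nearer 0.29/0.21), and a
  5-year incremental QALY of 0.046 against the reference 0.043. The interior
  points are exposed as `defaults.REMISSION_SCHEDULE` for users who prefer
  other interpolants.
- **Saving fraction s = 0.73.** This is higher than participant-level
  regressions of cost on remission would suggest (~0.45–0.5), but it is the
  value implied by the reference lifetime vs 5-year healthcare totals under
  the stated beyond-year-5 costing rule, and those totals are the calibration
  surface. The synthetic generator uses the same value for its remission /
  non-remission cost split so that cohort-estimated and packaged inputs
  agree.

The intervention cost components also cannot all be matched simultaneously:
the reference component rows sum to 1760 while the discounted total is 1691;
the package calibrates to the total and reports both discounted and
undiscounted component tables.

## 7. Synthetic cohort generator

The generator emulates the trial's data structure: two arms of 149
participants; exact-by-construction or Bernoulli-sampled 12-month remission
(46% / 5%); discrete annual relapse following the retention schedule; 2 %/yr
dropout (independent of remission by default, with a log-hazard-ratio knob
for informative-censoring experiments); 1% missed annual assessments;
gamma-distributed category costs; phase-by-year intervention resource use
with the reported means/SDs; and EQ-5D panels (baseline + years 1–2 for all,
years 3–5 for the ~58% intervention extension subgroup) with a true remission
increment of 0.037.

- **Cost frailty.** A per-participant mean-1 gamma frailty (SD 1.05)
  multiplies all category means, inducing cross-category and year-to-year
  cost correlation (~0.3). Without it, bootstrap uncertainty on 5-year cost
  sums is ~25% too narrow relative to the reference confidence intervals;
  chronically high-cost patients are a real feature of healthcare cost data.
  The conditional gamma SD is solved so the configured *marginal* SDs are
  preserved (property-tested).
- **Calibrated mode** (`calibrate=True`, the default for the base-case
  cohort) rescales sample moments to the configured cell values after
  drawing: exact remission counts, exact (arm, year, remission, category)
  cost-cell means, exact intervention resource means, and a fitted utility
  effect shifted onto its target. This emulates analysing *the* observed
  dataset whose summary statistics are known: point estimates anchor at the
  configured values while individual-level spread — and hence bootstrap
  uncertainty — is preserved. The i.i.d. mode (`calibrate=False`) is used for
  parameter-recovery studies, where sampling variability is the point.
- **Noise defaults.** EQ-5D baseline 0.70, subject SD 0.12, visit noise SD
  0.10. These keep ceiling clipping at the index maximum of 1.0 below ~5% of
  draws so that the configured effect is recoverable without attenuation;
  real EQ-5D data have a heavier ceiling, which a linear utility model would
  partially absorb into its coefficient.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: HbA1c/weight trajectories and their link to relapse;
medication-level prescribing; EQ-5D dimension profiles (only index values);
cost distributions with a point mass at zero within categories (gamma draws
are strictly positive when the mean is positive); correlation between
resource use and utility; and informative censoring (off by default).

## 8. Degenerate inputs and numerical conventions

Zero remission probability yields a zero schedule and a valid model run; a
bootstrap resample with no remitters is a valid draw (zero schedule), and
missing remission-status cost cells fall back to the arm mean scaled by
(1 − s). A constant-utility panel returns an exact zero effect. Ages beyond
the mortality or norm tables clamp to the last row (logged for norms).
Occupancy is conserved to 1e-12 by construction; the dead state is
non-decreasing. All randomness flows from a single integer seed per entry
point; identical seeds give byte-identical cohorts and PSA draws.

## 9. Problem sizes

Defaults used by the shipped analysis and the reproduction script: 149
participants per arm; 1000 PSA iterations; 100 independent cohorts for each
parameter-recovery average; a £0–£50,000 CEAC grid in £1,000 steps. The unit
test suite uses smaller cohorts (25–120 per arm) and iteration counts for the
structural checks, and full sizes where a headline quantity is asserted.

## 10. Known limitations

The sex-blended mortality approximation (§1); the linear-interpolation choice
for years 3–4 (§6); a remission cost-saving fraction tied to the calibration
surface rather than to participant-level cost regressions (§6); KM small-
sample bias under the stated missing-record rules (§2), kept small by the
low default missingness; and the absence of any weight-loss benefit channel
other than remission itself — cost and QALY gains attributable to weight
loss without remission are not modelled, which is conservative for the
intervention.
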