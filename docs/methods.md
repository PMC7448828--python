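# Methods

Model structure, assumptions, numerical choices, and limitations of the
`strokecea` cost-effectiveness model. Notation: mRS = modified Rankin
Scale (0 best … 5 worst disability, 6 = death); cycle length 0.25 years.

## 1. Decision problem

Two strategies for late-window (6–24 h) large-vessel-occlusion ischemic
stroke are compared per trial subgroup: mechanical thrombectomy plus
standard medical care (`MT_SMC`) and standard medical care alone
(`SMC`). The analysis takes a US healthcare-sector perspective, lifetime
horizon, with costs and QALYs discounted at 3% per year.

## 2. 90-day decision tree

Each arm's trial-observed 90-day mRS distribution `p = (p0 … p6)` fully
parameterizes the acute phase. Expected quantities are plain
expectations over the seven states:

* **Acute cost** = imaging + thrombolysis (`tpa_frequency × tpa_cost`)
  + (MT arm only) procedure + physician fee
  + severity-tiered 90-day care cost (tiers mRS 0–2, mRS 3–5, death).
  Imaging for SMC is CT + CTA; for MT it is CT + a CTA/MRA mix + a
  CTP/MRI mix + perfusion software, weighted by configured modality
  frequencies.
* **Expected utility** = `Σ p_i · u_i` with `u_6 = 0`.

Some trial publications report mRS 5 and 6 combined. Such arms carry a
6-element vector plus a combined tail; the tail is split proportionally
to the mRS 5:6 ratio of a designated reference distribution
(`mrs56_reference` in the study config). A zero-mass reference tail is a
validation error, not a silent fallback.

## 3. Lifetime Markov cohort model

90-day survivors enter states mRS 0–5 conditioned on survival
(`p_i / (1 − p6)`); death is absorbing. Cohort age advances 0.25 years
per cycle from the arm's mean age. Each cycle applies two competing
risks in a fixed order:

1. **Background mortality.** The annual life-table probability `qx`
   (sex-mixed by the arm's male fraction, age rounded down) is converted
   to a 3-month probability under an mRS-specific hazard ratio `h_i`:
   `q_cycle = 1 − exp(−h_i · (−ln(1 − qx)) / 4)`. Reference states
   mRS 0–1 have `h = 1`.
2. **Recurrent stroke** among those surviving step 1, with a fixed
   per-cycle probability equal across states. A recurring patient dies
   with the post-recurrence death probability (replacing background
   mortality for that fraction); survivors move to strictly worse mRS
   states, by default in equal shares (from mRS 5, survivors remain in
   mRS 5). Recovery to better states never occurs.

Accrual is end-of-cycle: patients who neither die nor recur accrue their
state's 3-month cost and `0.25 × utility` QALYs; patients who recur
accrue the recurrent-stroke cost and utility instead (see §4). With the
optional half-cycle correction, the accrual basis is the average of
start- and end-of-cycle occupancy, crediting dying/recurring patients
half a cycle. Discounting multiplies cycle `k` accruals by
`(1 + r)^(−0.25k)`. Acute-phase cost is added undiscounted at `t = 0`;
by default the first 90 days also contribute `0.25 ×` the acute expected
utility as undiscounted QALYs (flag `accrue_acute_qalys`).

The cohort runs until the alive fraction falls below `extinction_tol`
(default 10⁻⁶) or the cohort reaches `max_age` (default 110), where the
trace is truncated with a warning.

## 4. Recurrent-stroke cost and utility

Rather than sampling independent inputs, the per-event cost and utility
of a recurrent stroke are **derived from the decision tree of the same
strategy**: a recurrence is modeled as re-experiencing the acute phase,
so its cost equals the arm's expected 90-day acute cost and its
(cycle-length-weighted) utility equals the arm's expected acute utility.
These are recomputed per PSA draw so they co-vary with the sampled
inputs; an explicit override is supported for deterministic scenario
analysis.

## 5. Economic outputs

* **ICER** = Δcost/ΔQALY (MT_SMC − SMC). Negative Δcost with positive
  ΔQALY is labeled *dominant*; positive Δcost with negative ΔQALY
  *dominated*; |ΔQALY| < 10⁻¹² yields an *undefined* ICER (NaN). The
  signed ratio is always reported alongside the label.
* **NMB** = `wtp · ΔQALY − Δcost` (default wtp $100 000/QALY).
* **CEAC**: fraction of PSA draws with NMB > 0 over a wtp grid.

## 6. Probabilistic sensitivity analysis

Each uncertain input carries a distribution family in the study YAML:

| family       | use                              | parameterization |
|--------------|----------------------------------|------------------|
| `beta`       | probabilities                    | α, β directly, or moment-matched to base value and printed range with mean = base, sd = (high − low)/3.92 |
| `beta_pert`  | costs with min/mode/max ranges   | classic shape-4 PERT |
| `log_normal` | hazard ratios                    | median-preserving: `exp(N(ln base, se))` |
| `uniform`    | frequencies with flat ranges     | low, high |
| `dirichlet`  | mRS distributions                | concentration `n · p` (trial arm size × observed proportions) |
| `fixed`      | structurally fixed inputs        | point value |

Efficacy vectors are redrawn per draw from a Dirichlet whose
concentration is the arm's sample size times its observed distribution;
zero-probability categories stay at zero. The post-recurrence
equal-split weights are redrawn from a flat Dirichlet over the worse
states. Utility draws violating monotonicity across mRS states are
rejected and redrawn (capped; a cap hit is an error, not a silent
accept). Hazard ratios for the reference states mRS 0–1 are never
sampled. Draw `k` uses a dedicated child of `SeedSequence(seed)`, and
both strategies share each draw's parameter set (common random numbers),
so incremental results reflect parameter uncertainty, not sampling
noise between arms. A configuration in which every input is `fixed`
reproduces the deterministic run exactly.

## 7. One-way sensitivity analysis (tornado)

Each scalar input is set to its low and high bound (the printed range
when available, otherwise the distribution's central 95% interval) with
all else at base case, and the full model is re-evaluated. Entries are
ranked by absolute ICER spread; ranking by NMB spread is available for
dominance-heavy cases where ICER endpoints change sign. A composite
entry replaces the MT arm's whole 90-day mRS vector with configured
low/high efficacy scenarios.

## 8. Synthetic data generator — scope

The trials' per-subgroup mRS tables and the exact life table are not
redistributable, so `strokecea.synthetic` generates structural stand-ins:

* **Efficacy**: arm-level mRS vectors drawn from a Dirichlet around a
  standard-care baseline and a thrombectomy mean obtained by a
  proportional-odds (cumulative-logit) shift — the conventional one-knob
  ordinal treatment effect. The default shift (1.28 on the log
  cumulative-odds scale) was calibrated once so arm-level expected
  utilities land near 0.30 (SMC) and 0.49 (MT). One trial's records use
  the combined mRS 5+6 dialect, the other the separated dialect, so both
  input paths are exercised end to end.
* **Life table**: Gompertz form `qx = min(1, q0 · e^{k(age−60)})` with a
  female relative-risk factor, closed out with `qx = 1` at the terminal
  age.

Synthetic outputs reproduce realistic *structure*, not the trials'
actual numbers; all quantitative statements in this repository about
model results on synthetic inputs are labeled as such.

## 9. Numerical choices

* Deterministic cohort propagation in float64; occupancy conservation is
  asserted per cycle (tolerance 10⁻⁹).
* Life-table lookups clamp beyond the tabulated age range with a single
  warning per table instance.
* Per-subgroup PSA seeds are derived as
  `SHA-256("{master_seed}:{trial}/{label}")` truncated to 31 bits, so
  results are invariant to subgroup ordering and filtering.
* mRS distribution inputs are validated to sum to 1 within 10⁻⁶ and
  renormalized exactly.

## 10. Limitations

* Base-case results shipped here use synthetic efficacy and a synthetic
  life table; they are demonstrations of the pipeline, not estimates for
  real populations. Real inputs (per-arm mRS CSV, age/sex life-table
  CSV) are required for substantive conclusions.
* Recurrence risk is constant per cycle, equal across states, and
  time-invariant; post-recurrence severity follows an equal-split
  assumption over worse states.
* No recovery transitions: disability can only worsen after 90 days.
* Background mortality uses the cohort mean age and a fixed male
  fraction rather than individual-level age/sex distributions.
* Costs and utilities are time-invariant beyond the acute phase; no
  age-dependent utility decrement is applied.
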