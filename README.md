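# strokecea

Cost-effectiveness model of late-window mechanical thrombectomy plus
standard medical care (MT+SMC) versus standard medical care alone (SMC)
for acute ischemic stroke with large-vessel occlusion, from a US
healthcare-sector perspective.

## Scientific problem

The late-window thrombectomy trials (DAWN, DEFUSE 3) showed that patients
treated 6–24 hours after stroke onset end up substantially less disabled
at 90 days, measured on the modified Rankin Scale (mRS, 0 = no symptoms
… 5 = severe disability, 6 = death). Thrombectomy is expensive up front
(device, procedure, physician, additional imaging), but less disability
means lower long-term care costs and more quality-adjusted life-years
(QALYs). The economic question is whether the lifetime gain justifies the
acute cost: the incremental cost-effectiveness ratio (ICER, Δcost/ΔQALY)
against conventional US willingness-to-pay thresholds.

## Model

Two linked components, evaluated per strategy and per trial subgroup:

1. **90-day decision tree** — each arm's trial-observed 90-day mRS
   distribution fixes the probabilities; expected acute cost (imaging,
   thrombolysis, procedure, severity-tiered 90-day care) and expected
   utility are computed by expectation over the seven mRS states.
2. **Lifetime Markov cohort model** — 90-day survivors enter states
   mRS 0–5 and are propagated in 3-month cycles until cohort extinction.
   Each cycle applies, in order: background mortality (age/sex life
   table, scaled by mRS-specific hazard ratios), then recurrent stroke
   (fixed per-cycle probability; survivors of recurrence move to
   strictly worse states). State-specific 3-month costs and utilities
   accrue with 3%/year discounting; the cost and utility consequences of
   a recurrent stroke are derived from the decision tree itself.

Outputs: discounted lifetime cost and QALYs per strategy, ICER (with
dominance labels), net monetary benefit (NMB), probabilistic sensitivity
analysis (PSA) with cost-effectiveness acceptability curves (CEAC), and
one-way deterministic sensitivity analysis (tornado).

Because the trials' per-subgroup outcome tables and the exact life table
are not redistributable, the package ships a **synthetic data generator**
(`strokecea.synthetic`) producing statistically realistic stand-ins: mRS
distributions with a proportional-odds treatment effect, and a
Gompertz-form life table. Real inputs drop in as plain CSV/YAML files.

## Worked example

Run the bundled synthetic study (four subgroups, two per trial):

```python
from strokecea import fixture_base_case
from strokecea.runner import run_all

study = fixture_base_case(seed=12345)
res = run_all(study, modes={"deterministic"})
print(res.to_frame().to_string(index=False))
```

prints (synthetic inputs — illustrative, not trial results):

```
  trial        subgroup    delta_cost  delta_qaly          icer dominance           nmb
   DAWN full_population   4012.833907    0.884106   4538.861704            84397.744959
   DAWN      subgroup_1 -19848.746139    2.083408  -9527.055013  dominant 228189.582960
DEFUSE3 full_population -29045.170101    1.677355 -17316.059185  dominant 196780.621868
DEFUSE3      subgroup_1  40123.142682    1.941800  20662.856123           154056.899235
```

Adding a PSA for one subgroup:

```python
res = run_all(study, modes={"deterministic", "psa"}, seed=12345, n_draws=500,
              trial_filter="DEFUSE3", subgroup_filter="full_population")
r = res.results[0]
print(r.psa.summary()["delta_qaly"])
print(r.psa.prob_cost_effective(100_000.0))
```

```
{'mean': 1.7145123513989078, 'ci_low': 0.9184366212301868, 'ci_high': 2.5910264658565345}
1.0
```

i.e. thrombectomy gains a mean 1.71 discounted QALYs (95% interval
0.92–2.59) and is cost-effective at $100 000/QALY in 100% of 500 draws
for this synthetic subgroup.

Command line equivalents:

```bash
strokecea run  --seed 12345 --out-dir out/            # deterministic
strokecea psa  --seed 12345 --draws 2000 --out-dir out/
strokecea owsa --seed 12345 --out-dir out/            # tornado
strokecea all  --seed 12345 --out-dir out/
strokecea make-fixture --seed 12345 --out-dir my_study/   # editable YAML+CSV study
strokecea run --config my_study/study.yaml --out-dir out/
```

Each run writes `results.csv`, per-subgroup `psa_*.csv` / `ceac_*.csv` /
`tornado_*.csv`, and `run_metadata.json` (seed, versions, config hash).

## Reproducing results

* Everything is seeded. `run_all(..., seed=S)` derives one independent,
  order-invariant stream per subgroup (SHA-256 of `"{seed}:{trial}/{label}"`),
  so the same seed gives bit-identical results regardless of subgroup
  order or filtering.
* `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the headline quantities: fixed-input consistency checks
  (post-recurrence transition probabilities, ICER/NMB arithmetic,
  decision-tree scenario utilities), PSA sampler means at 10⁵ draws, and
  the full synthetic base-case study (deterministic + 500-draw PSA).
* To use real inputs, replace `efficacy.csv` (per-arm 90-day mRS
  distributions; combined mRS 5+6 columns are supported) and
  `life_table.csv` (age/sex/qx) in a `make-fixture` output directory and
  re-run with `--config`. All cost, utility, and transition inputs,
  including their uncertainty distributions, live in the study YAML.

See `docs/methods.md` for the full model description, assumptions, and
limitations.
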