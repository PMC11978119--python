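# lifexpect

Life expectancy, loss of life expectancy and lifetime healthcare cost for
registry cancer cohorts, by relative-survival extrapolation.

Registry follow-up is usually a decade; remaining lifetimes span several.
`lifexpect` bridges the gap the way registry LE studies do: it simulates a
Monte Carlo reference group matched to each patient's sex, age and calendar
year from a national life table, estimates patient survival month-by-month
with the Kaplan–Meier estimator, and extrapolates the **logit of the
survival ratio**

&nbsp;&nbsp;&nbsp;&nbsp;W(t) = logit( S_p(t) / S_r(t) )

to the lifetime horizon with a rolling restricted-cubic-spline one-step
predictor: fit W on a window of recent months, predict the next month, set
S_p(t+1) = expit(Ŵ)·S_r(t+1), treat the prediction as data, drop the
window's oldest month and repeat until survival reaches zero. Then

- **LE** = area under the extrapolated patient curve (years),
- **loss of LE** = referent LE − patient LE,
- **lifetime cost** = Σ_t ½(S(t−1)+S(t)) · μ(t) · (1+r)^(−t/12) / X,

where μ(t) is the mean monthly cost function with an elevated terminal
profile over the last K months of life, r the annual discount rate (3%)
and X the exchange rate (30.93 TWD/USD). Strata whose survival is not
materially and significantly worse than the referents are *refused* —
extrapolated loss of LE is undefined there, and the tables show "–", the
behaviour early-stage strata exhibit in national data.

The package is organised as an analysis project: every computation lives in
`src/lifexpect` (cohort model and stratification, life table and referent
simulation, monthly KM, rolling extrapolation, cost model, bootstrap SEs,
reporting, synthetic registry with exact ground truth), with numbered
drivers under `analysis/` and validation studies importable from
`lifexpect.studies`. Because the source registries of such studies are not
redistributable, the synthetic module is first-class: it generates
registry-shaped cohorts, costs and life tables with known truth so every
stage is verifiable end to end.

## Worked example

```python
from lifexpect import (AnalysisConfig, GeneratorConfig, simulate_cohort,
                       simulate_costs, make_life_table, estimate_stratum,
                       Cohort, assign_strata)

cfg = GeneratorConfig(n_patients=15000, seed=7)          # study-like registry
table = make_life_table(cfg.gompertz_b, cfg.gompertz_theta,
                        years=range(2008, 2020))
cohort, truth = simulate_cohort(cfg, table=table)
costs = simulate_costs(cohort, cfg)

df = assign_strata(cohort)                               # age band x stage
sel = (df["age_band"] == "65-74") & (df["stage"] == "4")
stratum = Cohort(df[sel].reset_index(drop=True), cohort.censor_date)
est = estimate_stratum(stratum, costs, table,
                       AnalysisConfig(bootstrap_B=0), seed=11)
print(f"n={est.n}  LE={est.le:.2f} y  loss of LE={est.loss_le:.2f} y  "
      f"lifetime cost=${est.lifetime_cost_usd:,.0f}")
```

prints

```
n=2018  LE=8.77 y  loss of LE=7.37 y  lifetime cost=$52,755
```

for the metastatic 65–74 stratum of this seed: patients live 8.8 years on
average from diagnosis, 7.4 years less than their matched referents, and
accrue about $53k of discounted healthcare cost over the remaining
lifetime (the generator's exact truth for the whole stage-4 stratum is
LE 8.68 y, loss 6.77 y, $50.6k — single-stratum draws scatter around it). The same analysis across all strata and axes:

```bash
python analysis/01_simulate_registry.py     # synthetic registry -> scratch/data
python analysis/02_stratified_estimates.py  # summary tables -> results/
python analysis/03_recovery_and_null.py     # recovery vs truth, null refusal
python analysis/04_uncertainty.py           # bootstrap coverage + scaling
python analysis/05_published_composition.py # published-composition arithmetic
```

or, on real CSVs with the documented schemas, via the CLI:

```bash
lifexpect run --cohort cohort.csv --costs costs.csv \
              --lifetable lt.csv --config config.yaml --out results/
```

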