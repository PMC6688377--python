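# orthocost

Patient-level Monte Carlo simulation of the long-term preventive-dentistry
costs caused by enamel damage from fixed orthodontic appliances — white-spot
lesions (WSL) and enamel cavitations — comparing conventional **labial**
(outer-surface) with **lingual** (tongue-side) multi-bracket treatment under
the German private dental fee catalogue (GOZ).

It is aimed at orthodontists, health-economics researchers and students who
want a reproducible, testable implementation of this kind of cost
microsimulation: every distributional assumption is an explicit, seeded
sampler with an analytic oracle beside it.

## The model

For each of *n* simulated patients (default 10⁶):

1. **Treatment**: age at appliance placement `age ~ U(12, 18)` years,
   treatment duration `d ~ U(9, 45)` months.
2. **Enamel defects at debonding**: WSL and cavitation counts are drawn
   independently from negative binomials in the size/mean parameterization,
   `X ~ NB(size = k, mean = r·d)` with `P(X = 0) = (k / (k + r·d))^k`,
   capped at 24 bracket-bearing teeth.  Per-month incidence rates *r* and
   dispersions *k* differ by appliance:

   |                   | lingual | labial |
   |-------------------|---------|--------|
   | WSL rate /mo      | 0.0248  | 0.1537 |
   | WSL dispersion    | 0.3     | 0.72   |
   | cavitation rate /mo | 0.0012 | 0.0015 |
   | cavitation dispersion | 1   | 1      |

3. **Residual lifetime** after debonding: shape-1 Weibull (exponential)
   with median 696 months (58 years), truncated at age 100.
4. **Treatment and repair**: every cavitation — and, for labial patients,
   every WSL — receives a single-surface composite restoration at
   debonding.  Each restored surface then undergoes an exponential repair
   chain with configurable median time to re-restoration (60/120/180/372
   months), capped at 5 repairs, while the cumulative repair time undercuts
   the residual lifetime.  Lingual WSL are esthetically irrelevant and get
   one topical fluoridation, never repaired.
5. **Costs** (GOZ, factors 2.3 / 3.5): fluoridation 6.47 / 9.84 Eur,
   restoration 84.99 / 129.34 Eur per placement and per repair cycle.
   Costs are undiscounted face values.

Summary metrics per scenario report mean itemized costs three ways: over all
patients, over patients with ≥ 1 WSL and/or cavitation (*pop1*), and over
patients with ≥ 1 cavitation (*pop2*).

## Worked example

```python
from orthocost import CohortParams, INTERVENTIONS, ScenarioConfig, run_scenario

for name in ("labial", "lingual"):
    s = run_scenario(ScenarioConfig(
        intervention=INTERVENTIONS[name],
        fee_factor=3.5,
        repair_median=180.0,          # 15-year composite survival scenario
        cohort=CohortParams(n_sim=1_000_000),
        seed=20190809,
    ))
    print(f"{s.intervention:8s} pop1_frac={s.frac_pop1:.3f} "
          f"mean_wsl={s.mean_n_wsl:.3f} all={s.all_patients.total:.2f} "
          f"pop1={s.pop1.total:.2f} pop2={s.pop2.total:.2f}")
```

prints

```
labial   pop1_frac=0.737 mean_wsl=4.026 all=1719.81 pop1=2334.36 pop2=2380.36
lingual  pop1_frac=0.307 mean_wsl=0.668 all=20.21 pop1=65.83 pop2=444.27
```

Read: 73.7 % of labial patients leave treatment with at least one enamel
defect (on average 4.0 WSL), and lifetime treatment + re-treatment costs
average ≈ 1720 Eur per labial patient (≈ 2334 Eur among affected patients),
versus ≈ 20 Eur per lingual patient — the cost asymmetry that makes lingual
appliances economically competitive despite higher upfront fees.

The same is available from the shell:

```sh
orthocost simulate --intervention labial --fee-factor 3.5 --repair-median 180
orthocost grid --table 3 --n-sim 100000 --out-csv table3.csv
orthocost validate        # samplers vs their analytic oracles
```

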