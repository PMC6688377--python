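# Methods

## Model structure

`orthocost` is a patient-level cost microsimulation.  Each simulated patient
is an independent draw from a five-stage generative model; no interaction
between patients exists, so the whole cohort is vectorized.

**1. Orthodontic intervention.**  Age at appliance placement is continuous
uniform on [12, 18] years; treatment duration is continuous uniform on
[9, 45] months (mean and median 27 months, so about half of all simulated
treatments finish in under 27 months).  Both are modelling choices that
bracket the adolescent treatment window reported by the large incidence
studies the rates derive from; the identical duration distribution for both
appliances deliberately removes duration as a confounder in the cost
comparison.

**2. Defect counts.**  WSL and cavitation counts at debonding are negative
binomial in the ecological size/mean parameterization — the one R's
`rnbinom(size, mu)` uses — with mean `rate × duration` and zero probability
`(size/(size+mean))^size`.  The per-month rates (lingual 0.0248 WSL,
0.0012 cavitation; labial 0.1537 WSL, 0.0015 cavitation) and dispersions
(0.3 / 0.72 for WSL, 1 for cavitations) are taken as fixed inputs.  The
dispersion controls the defect-free fraction at a fixed mean; dispersion 1
makes cavitation counts geometric.  Counts are capped at 24 teeth (incisors
through first molars in both arches); the cap is applied to WSL and
cavitations independently — the joint-vs-independent choice is numerically
irrelevant because cavitation means are ~0.03–0.04.  WSL and cavitation
counts are conditionally independent given duration; no correlation
structure is modelled.

**3. Residual lifetime.**  Time from debonding to death is shape-1 Weibull,
i.e. exponential with scale `696/ln 2 ≈ 1004` months (median 696 months =
58 years, a mortality-table summary for the cohort's age).  Draws are
clamped so that age at placement + treatment duration + residual lifetime
never exceeds 100 years; the clamp truncates without renormalizing.  The
clamp binds for roughly a third of draws in the far tail and materially
lowers repair counts in the long-repair-median scenarios, so it is not a
cosmetic detail.

**4. Repair chains.**  Every cavitation, and every labial WSL, is restored
with a single-surface composite at debonding (time 0 of residual life).
Each restored surface then generates repairs: successive inter-repair times
are exponential with median `m ∈ {60, 120, 180, 372}` months, and a repair
occurs while the cumulative repair time is strictly below the residual
lifetime, up to 5 repairs per surface.  Because exponential gaps form a
Poisson process, the chain length is exactly `min(N, 5)` with
`N ~ Poisson(ln 2 · residual / m)`; the implementation draws the Poisson
count directly (the sequential cumulative-sum route is also implemented and
tested for distributional identity).  The two evidence-based medians are
180 months (50 % composite failure at 15 years) and 372 months (80 %
survival at 10 years ⇒ exponential median −log 0.5/(−log 0.8/10) = 31.06 y,
carried as the rounded 31 y × 12 = 372 months); 60 and 120 months model
esthetically driven early renewal.  Lingual WSL receive one topical
fluoridation and never enter the repair process.

**5. Costs.**  GOZ fee items are stored as exact decimal cents at the two
printed increment factors — fluoridation (GOZ 1020) 6.47/9.84 Eur;
restoration (GOZ 2030 + 2040 + 2060) 8.41 + 8.41 + 68.17 = 84.99 Eur at 2.3
and 12.80 + 12.80 + 103.74 = 129.34 Eur at 3.5.  Only final per-factor
amounts are modelled (catalogue point values are not used).  Per-patient
costs are count × fee, with one restoration fee per repair cycle, summed in
floating point (error orders of magnitude below the cent).  No discounting
and no fee growth are applied — future repairs cost their face value — and
no anaesthesia, radiograph, multi-surface, veneer or crown positions exist
in the model.

## Summary metrics

Each scenario reports defect prevalence and mean itemized costs in three
population framings: all patients, patients with ≥ 1 WSL and/or cavitation
(pop1) and patients with ≥ 1 cavitation (pop2 ⊆ pop1).  Subgroup means
divide by the subgroup size; empty subgroups report NaN rather than 0 so
that small smoke-scale runs cannot silently bias means.  In-run Monte Carlo
standard errors accompany the key means (patient-level sample SD / √n).
The algebraic identities `all-patient mean = pop1 fraction × pop1 mean` and
`total = initial + re-treatment` per component hold exactly and are tested.

## Randomness and reproducibility

One `numpy` Generator per scenario, with a fixed draw order: ages,
durations, WSL counts, cavitation counts, residual lifetimes, WSL repair
chains, cavitation repair chains.  A scenario seed therefore pins down every
array bit-for-bit.  Grid runs derive per-scenario seeds from one master seed
as the words of `SeedSequence(master).generate_state(n)` masked to 31 bits,
giving mutually independent streams from a single integer.  Default seeds
are arbitrary fixed constants.

## Verification strategy

Stochastic components are checked against closed forms rather than golden
numbers: the NB zero probability (and its quadrature average over the
uniform duration) for defect counts, the truncated-Poisson expectation
`Σ_{k<5} k·P(N=k) + 5·P(N≥5)` for repair chains, exponential
memorylessness and the median for lifetimes, and the NB → Poisson limit at
large dispersion.  `orthocost validate` runs these oracle checks from the
command line and prints deviations in standard-error units.

At full scale (10⁶ patients) the simulation reproduces the published
scenario grid within Monte Carlo tolerance for all WSL-driven quantities
(e.g. labial/3.5/180-month all-patient mean ≈ 1719 Eur, affected-patient
mean ≈ 2333 Eur, affected fractions 0.736/0.308, mean WSL counts
4.02/0.67).

## Known limitations

- **Rounded cavitation rates.**  The published cavitation incidence rates
  carry two significant figures (0.0012/0.0015 per month), while the
  published result tables imply unrounded values near 0.00117/0.00148.
  Simulating with the printed rates biases cavitation means about +2 %
  (0.0327 vs printed ≈ 0.0317 lingual), which propagates into
  cavitation-dominated cost metrics: the lingual all-patient mean lands
  near 20.3 Eur against the printed 19.94 Eur.  This is a fixed ~2 % offset
  inherited from input rounding, not Monte Carlo noise; the acceptance
  tests that pin those three quantities to 3 in-run SE document it by
  failing, and all other checks pass.
- The generator emulates the study conditions, not real claims data: real
  cohorts have correlated WSL/cavitation risks, non-uniform ages and
  durations, escalation to multi-surface restorations or crowns with
  repeated repair, partial non-treatment of WSL, and payer heterogeneity.
  Passing tests show the simulator reproduces its specified stochastic
  model, not that the model predicts individual patients' costs.
- Costs are undiscounted and fee levels static, so multi-decade totals
  overweight distant repairs relative to a discounted analysis.
- Appliance, laboratory and periodontal-complication costs are out of
  scope, as are anaesthesia and radiograph fee positions.

## Problem sizes

Default cohorts are 10⁶ patients per scenario (a full scenario takes on the
order of a second; the 16-scenario grid well under a minute).  Distribution-
level unit tests use 10⁵–2·10⁵ draws, where 3-SE bands are tight enough to
catch parameterization mistakes; the grid smoke test runs 16 × 10⁴ patients
and asserts schema only.
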