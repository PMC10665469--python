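# Methods

## Model structure and assumptions

The simulation is a deterministic discrete-time Markov cohort (macro)
model. A closed cohort — the total Japanese population of all ages in 2019,
no births or migration — occupies four mutually exclusive states: healthy,
acute CVD (hospitalised), chronic CVD (outpatient survivors), and dead
(absorbing). Cycles are annual; the default horizon is 10 years.

Structural assumptions, chosen to match the published framework:

- **Initial split.** The acute pool at baseline holds one year of incident
  cases (incidence × population); the chronic pool holds the remaining
  prevalent cases (prevalence − incidence); everyone else is healthy. This
  uses only published quantities and treats prevalence as the total
  alive-with-CVD pool.
- **Acute resolves in one cycle.** There is no acute self-loop: an acute
  patient either survives to discharge (→ chronic) or dies of the disease
  within the year.
- **No return to health.** Once CVD occurs, people remain in the
  acute/chronic/dead subsystem.
- **Uniform non-CVD mortality.** The annual probability of dying from
  non-CVD causes, `(total deaths − CVD deaths)/population`, applies equally
  to the healthy and chronic states.
- **Rates as probabilities.** Annual per-100,000 rates are used directly as
  annual probabilities without a hazard (exponential) conversion; at the
  magnitudes involved (≤ 0.0135/yr) the difference is far below the other
  model uncertainty.
- **Immediate full effect.** Each year's cumulative salt reduction takes
  full effect on risks within that year (no phase-in lag).
- **No half-cycle correction.** Occupancies are end-of-cycle counts; the
  choice is recorded in `RunSettings.half_cycle_correction` so it is visible
  in configs.

## Policy effects

Each policy removes a stated percentage of baseline salt intake over a
decade (media campaign and labeling 2%, voluntary reformulation 15%,
mandatory reformulation 20%). Intake is assumed to fall at a constant annual
rate, i.e. linearly in percentage points of baseline (`E/duration` per
year — 0.2/1.5/2.0 %/yr for a 10-year horizon), rather than compounding;
the linear reading is what reproduces those printed annual figures. Salt
(NaCl) is converted to sodium by molar-mass ratio 22.99/58.44 because the
relative risks are expressed per unit of sodium.

Percent risk changes compose **linearly** in the cumulative sodium
reduction by default (`m = 1 − pct·ΔNa`), with a config-switchable
log-linear alternative (`m = exp(−pct·ΔNa)`) for sensitivity; at the deltas
reachable here (< 1 g Na/day) the two differ in the third decimal. Linear
multipliers that would reach zero raise an error rather than silently
flooring; a configurable floor (default 0.05) guards downstream row sums.
The incidence multiplier scales both first-ever (healthy→acute) and
recurrent (chronic→acute) events; the mortality multiplier scales acute
case fatality only.

## Economics

- **Costs.** England-scale policy plus monitoring costs (GBP) are multiplied
  by a population-scaling factor of 2 (the stated round factor; the exact
  population ratio ≈ 2.123 can be configured instead), divided by the
  horizon into a constant annual stream, and converted at 0.783 GBP/USD.
  Labeling's policy cost is 20,000 product lines × 1,000 GBP; worst-case
  mandatory reformulation is 20,000 lines × 25,000 GBP; voluntary and
  best-case mandatory reformulation carry no policy cost. When configured
  identically, best-case mandatory and voluntary costs are exactly equal
  (the 0.2 M USD difference in the published totals is unexplained there
  and is not reproduced).
- **Benefits.** National CVD inpatient expenditure is assigned to the acute
  state and outpatient expenditure to the chronic state. Unit costs per
  person-year are fixed at baseline (expenditure / baseline occupancy; with
  defaults, ≈ 22,757 USD acute and ≈ 1,401 USD chronic) — no unit-cost
  inflation — so benefits arise purely from occupancy differences between
  the null and policy trajectories, reported with acute/chronic attribution.
- **Discounting.** 2%/yr by default over 0–4% sweeps; end-of-cycle
  convention (first accrual divided by 1.02), switchable to begin-of-cycle.
  Net benefit is benefit minus cost, accumulated over the horizon.

## Parameters

| Parameter | Default | Units | Source class |
|---|---|---|---|
| Total population | 126,197,000 | persons | published |
| Total deaths | 1,381,093 | /yr | published |
| Mean salt intake | 10.1 | g NaCl/day | published |
| CVD incidence | 1,203 (1,128–1,283) | /100,000/yr | published |
| CVD prevalence | 13,500 (12,956–14,064) | /100,000 | published |
| CVD mortality | 291 (231–326) | /100,000/yr | published |
| RR, incidence | 6 (1–11) | % per g Na/day | published |
| RR, mortality | 1 (0.2–1.7) | % per 10 mmol Na/day | published |
| Inpatient expenditure | 34,549,123,934 | USD/yr | published |
| Outpatient expenditure | 21,747,546,097 | USD/yr | published |
| Acute case fatality | 0.10 | /yr | placeholder |
| Chronic recurrence | 0.05 | /yr | placeholder |
| Media-campaign policy cost | 35 M | GBP (England) | placeholder |
| Monitoring cost | 20 M (2 M/yr) | GBP over decade | placeholder |
| Discount rate | 0.02 | /yr | published |
| GBP/USD, JPY/USD | 0.783, 109.01 | 2019 averages | published |

Placeholders exist because the exact transition probabilities and monitoring
line items are not printed in the public sources; they were chosen as
round, literature-plausible magnitudes (acute CVD case fatality near 10%,
recurrence near 5%/yr, monitoring a small fraction of campaign-scale
spending) and are flagged `provenance: "not from paper"` in the exported
parameter table and in run-time warnings. Every quantity that *is* printed
is stored verbatim and string-matchable.

## Synthetic parameter sets and the verification oracle

`fixtures.perturbed_configs` applies uniform multiplicative jitter
(default ±20%) to every numeric parameter, resampling draws that violate an
invariant (e.g. prevalence falling below incidence), with a fixed seeded
generator so outputs are reproducible. Uniform multiplicative jitter keeps
positivity automatically. These sets emulate parameter uncertainty only:
they do not emulate age/sex structure, blood-pressure mediation, secular
trends, or correlated parameter errors, so passing tests demonstrate
engine correctness across the parameter space, not real-world calibration.

`fixtures.oracle_run` recomputes trajectories with explicit per-state
scalar arithmetic and inline multiplier formulas, sharing no matrix code
with the engine. Engine/oracle agreement to 1e-9 relative error per cell
across perturbed configs × scenarios is the package's central correctness
property (measured agreement is ~1e-15).

## Numerical choices

- Occupancies are continuous person counts (no integer rounding).
- Row sums of transition matrices are checked to 1e-12; cohort conservation
  to 1e-6 relative.
- Ties in the tornado ranking keep sweep-definition order (stable sort).
- Sweeping a point-with-bounds parameter moves its point estimate and widens
  the stored bounds if the swept value escapes them, keeping the config
  valid; the sweep never mutates the caller's config.
- Degenerate inputs fail loudly: negative masses, multipliers outside
  [0, 1], overfull matrix rows, zero baseline occupancy in unit-cost
  construction, and mismatched trajectory horizons all raise with the
  offending field or row named.

## Known limitations

- No age/sex stratification, no blood-pressure mediation step, no open
  cohort, no microsimulation, no QALYs/DALYs or productivity effects, and
  no probabilistic sensitivity analysis — deliberate scope limits.
- One-way sweeps perturb parameters independently (no joint consistency
  between incidence, prevalence, and mortality).
- With placeholder transition probabilities, absolute monetary outputs are
  illustrative; structural results (orderings, equalities, monotonicities,
  signs) are the robust outputs. In particular, because every benefit
  channel scales approximately linearly with the incidence relative risk,
  the one-way sweep over its wide uncertainty interval (1–11 around 6)
  produces the widest tornado bar in this implementation, ahead of the
  policy-effect and discount-rate sweeps.
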