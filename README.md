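# saltpolicy

A Markov cohort cost–benefit model of population-level dietary salt-reduction
policies, parameterised for the Japanese population of 2019 with policy costs
and effects taken from England's national salt-reduction programme.

It is written for health-economics and public-health researchers who want a
transparent, config-driven alternative to spreadsheet or proprietary
decision-tree implementations of this class of model: every parameter is a
plain YAML value with recorded provenance, every stage is a tested function,
and an independent brute-force oracle verifies the simulation engine.

## The model

A closed national cohort of N = 126,197,000 people moves among four mutually
exclusive health states — *healthy*, *acute CVD*, *chronic CVD*, *dead* — in
annual cycles over a 10-year horizon. At baseline the cohort is split using
CVD incidence (acute pool), prevalence minus incidence (chronic pool), and
the remainder (healthy). Each cycle applies a row-stochastic transition
matrix P(t):

- healthy → acute: CVD incidence `i·m_inc(t)`; healthy → dead: non-CVD
  mortality `q = (D_total − D_CVD)/N`;
- acute resolves within one cycle: acute → dead with case fatality
  `f·m_mort(t)`, otherwise acute → chronic;
- chronic → acute with recurrence `r·m_inc(t)`; chronic → dead with `q`;
- dead is absorbing, and no state returns to healthy.

A policy that removes `E` % of baseline salt intake over the decade lowers
intake linearly by `E/10` percentage points per year. The cumulative salt
reduction is converted to sodium (×22.99/58.44) and mapped to risk
multipliers through published relative risks:

    m_inc(t)  = 1 − (RR_inc/100) · Δ Na g(t)          (RR_inc = 6 %/g, CI 1–11)
    m_mort(t) = 1 − (RR_mort/100) · Δ Na mmol(t)/10   (RR_mort = 1 %/10 mmol, CI 0.2–1.7)

Benefits are averted healthcare expenditures: national inpatient spending is
assigned to the acute state and outpatient spending to the chronic state,
fixing per-person-year unit costs at their baseline values; year-t benefit is
the unit-cost-weighted occupancy gap between the no-policy and policy runs.
Costs are the England policy + monitoring costs, doubled for population
scale, annualised over the horizon, and converted at 2019 exchange rates.
Both streams are discounted at 2%/yr and accumulated into the net benefit
(benefit − cost). One-way sensitivity sweeps over the published uncertainty
intervals produce a tornado-ranked table.

Transition probabilities that the published sources do not print (acute case
fatality, chronic recurrence, monitoring cost line items) ship as documented
placeholders tagged `provenance: "not from paper"`; the model warns whenever
they are in use, and they are meant to be overridden from a config file.

## Worked example

```python
from saltpolicy import baseline_config, cumulative_net_benefit

cfg = baseline_config()
for name in cfg.scenario_names:
    nb = cumulative_net_benefit(cfg, cfg.scenario(name))
    print(f"{name:16s} cost {nb.cumulative_cost/1e6:8.1f} M USD  "
          f"benefit {nb.cumulative_benefit/1e6:8.1f} M USD  "
          f"net {nb.cumulative_net_benefit/1e6:8.1f} M USD")
```

prints (cumulative discounted totals over 10 years):

```
media_campaign   cost    126.2 M USD  benefit   1169.1 M USD  net   1042.9 M USD
labeling         cost     91.8 M USD  benefit   1169.1 M USD  net   1077.3 M USD
voluntary        cost     45.9 M USD  benefit   8771.2 M USD  net   8725.3 M USD
mandatory_best   cost     45.9 M USD  benefit  11696.6 M USD  net  11650.7 M USD
mandatory_worst  cost   1193.1 M USD  benefit  11696.6 M USD  net  10503.5 M USD
```

Mandatory reformulation (best-case cost) dominates; media campaign and
labeling share one benefit stream (identical 2% decade effect) and differ
only in cost; the two mandatory cost cases share one benefit stream. The
absolute benefit magnitudes depend on the placeholder case-fatality and
recurrence probabilities and should be read as illustrative until those are
replaced with study-specific values.

The same pipeline is available from a shell:

```sh
saltpolicy run --out results/run            # all scenarios, default inputs
saltpolicy sensitivity --scenario mandatory_best --out results/sens
saltpolicy fixtures generate --n 10 --seed 1 --out results/configs
```

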