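"""Intervention costs, averted-expenditure benefits, discounting, net benefit.

Costs: the England-scale policy cost plus decade monitoring cost is scaled to
the Japanese population (default factor 2), spread evenly over the horizon,
and converted from GBP to USD.  Benefits: national inpatient expenditure is
assigned to the acute state and outpatient expenditure to the chronic state;
per-person-year unit costs are fixed at their baseline values, so benefits
arise purely from occupancy differences between the null and policy
trajectories.  Both streams are discounted (end-of-cycle by default) and
accumulated into a net benefit series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EconomicParams, ModelConfig, PolicyScenario
from .markov import StateVector, Trajectory, initial_state, run_cohort


@dataclass(frozen=True)
class UnitStateCosts:
    """Healthcare cost per person-year in the acute and chronic states, USD."""

    acute_usd_per_person_year: float
    chronic_usd_per_person_year: float


def annual_intervention_cost(
    scenario: PolicyScenario, econ: EconomicParams, horizon: int
) -> float:
    """Constant annual intervention cost in USD.

    population_scaling x (policy + monitoring cost, GBP) / horizon,
    converted at the configured GBP/USD rate.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    total_gbp = scenario.population_scaling * (
        scenario.policy_cost_gbp + scenario.monitoring_cost_gbp
    )
    return total_gbp / horizon / econ.gbp_per_usd


def unit_state_costs(econ: EconomicParams, baseline_state: StateVector) -> UnitStateCosts:
    """Per-person-year state costs from national expenditure / baseline occupancy."""
    if baseline_state.acute <= 0 or baseline_state.chronic <= 0:
        raise ValueError("baseline acute and chronic occupancies must be positive")
    return UnitStateCosts(
        acute_usd_per_person_year=econ.inpatient_expenditure_usd / baseline_state.acute,
        chronic_usd_per_person_year=econ.outpatient_expenditure_usd
        / baseline_state.chronic,
    )


def benefit_stream(
    null_traj: Trajectory, scen_traj: Trajectory, units: UnitStateCosts
) -> pd.DataFrame:
    """Yearly averted expenditure (USD) with acute/chronic attribution.

    Year-t benefit compares end-of-cycle occupancies of the null and policy
    runs; rows cover years 1..horizon (cycle 0 is shared).
    """
    if null_traj.horizon != scen_traj.horizon:
        raise ValueError("trajectories must share the same horizon")
    if not np.isclose(null_traj.initial_total, scen_traj.initial_total):
        raise ValueError("trajectories must share the initial population")
    years = np.arange(1, null_traj.horizon + 1)
    d_acute = (null_traj.occupancy("acute") - scen_traj.occupancy("acute"))[1:]
    d_chronic = (null_traj.occupancy("chronic") - scen_traj.occupancy("chronic"))[1:]
    benefit_acute = units.acute_usd_per_person_year * d_acute
    benefit_chronic = units.chronic_usd_per_person_year * d_chronic
    return pd.DataFrame(
        {
            "year": years,
            "benefit_acute": benefit_acute,
            "benefit_chronic": benefit_chronic,
            "benefit": benefit_acute + benefit_chronic,
        }
    )


def discount_stream(
    stream: np.ndarray, rate: float, convention: str = "end"
) -> np.ndarray:
    """Discount a year-1..horizon stream to present value.

    End-of-cycle convention divides year t by (1+rate)^t; begin-of-cycle by
    (1+rate)^(t-1).  Rate 0 is the identity.
    """
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    stream = np.asarray(stream, dtype=float)
    t = np.arange(1, len(stream) + 1)
    if convention == "end":
        factors = (1.0 + rate) ** (-t)
    elif convention == "begin":
        factors = (1.0 + rate) ** (-(t - 1))
    else:
        raise ValueError(f"unknown discount convention {convention!r}")
    return stream * factors


@dataclass(frozen=True)
class NetBenefitSeries:
    """Per-year and cumulative discounted costs, benefits, and net benefits."""

    scenario: str
    table: pd.DataFrame  # year, cost, benefit, benefit_acute, benefit_chronic,
    #                      disc_cost, disc_benefit, disc_net, cum_* columns

    @property
    def cumulative_cost(self) -> float:
        return float(self.table["cum_cost"].iloc[-1])

    @property
    def cumulative_benefit(self) -> float:
        return float(self.table["cum_benefit"].iloc[-1])

    @property
    def cumulative_net_benefit(self) -> float:
        return float(self.table["cum_net_benefit"].iloc[-1])

    def benefit_state_shares(self) -> dict[str, float]:
        """Share of total (undiscounted) benefit accruing in each state."""
        total = float(self.table["benefit"].sum())
        if total == 0:
            return {"acute": 0.0, "chronic": 0.0}
        return {
            "acute": float(self.table["benefit_acute"].sum()) / total,
            "chronic": float(self.table["benefit_chronic"].sum()) / total,
        }

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["scenario"] = self.scenario
        return out

    def summary(self) -> dict:
        shares = self.benefit_state_shares()
        return {
            "scenario": self.scenario,
            "cumulative_cost_usd": self.cumulative_cost,
            "cumulative_benefit_usd": self.cumulative_benefit,
            "cumulative_net_benefit_usd": self.cumulative_net_benefit,
            "benefit_share_acute": shares["acute"],
            "benefit_share_chronic": shares["chronic"],
        }


def cumulative_net_benefit(cfg: ModelConfig, scenario: PolicyScenario) -> NetBenefitSeries:
    """Run null and policy trajectories and compose the full benefit series."""
    null_traj = run_cohort(cfg, None)
    scen_traj = run_cohort(cfg, scenario)
    units = unit_state_costs(cfg.economics, initial_state(cfg.epidemiology))
    bens = benefit_stream(null_traj, scen_traj, units)

    horizon = cfg.horizon_years
    cost = np.full(
        horizon, annual_intervention_cost(scenario, cfg.economics, horizon)
    )
    rate = cfg.economics.discount_rate
    conv = cfg.settings.discount_convention
    disc_cost = discount_stream(cost, rate, conv)
    disc_benefit = discount_stream(bens["benefit"].to_numpy(), rate, conv)
    disc_net = disc_benefit - disc_cost

    table = bens.assign(
        cost=cost,
        net_benefit=bens["benefit"] - cost,
        disc_cost=disc_cost,
        disc_benefit=disc_benefit,
        disc_net_benefit=disc_net,
        cum_cost=np.cumsum(disc_cost),
        cum_benefit=np.cumsum(disc_benefit),
        cum_net_benefit=np.cumsum(disc_net),
    )
    return NetBenefitSeries(scenario=scenario.name, table=table)
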