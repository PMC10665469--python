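"""Cost streams, averted-expenditure benefits, discounting, net benefit."""

import numpy as np
import pytest

from saltpolicy import (
    annual_intervention_cost,
    benefit_stream,
    cumulative_net_benefit,
    discount_stream,
    initial_state,
    run_cohort,
    unit_state_costs,
)
from saltpolicy.config import PolicyScenario
from saltpolicy.economics import UnitStateCosts
from saltpolicy.markov import StateVector, Trajectory


def _scenario(pct=0.0, policy=0.0, monitoring=0.0, name="toy"):
    return PolicyScenario(
        name=name,
        ten_year_salt_reduction_pct=pct,
        policy_cost_gbp=policy,
        monitoring_cost_gbp=monitoring,
    )


class TestInterventionCost:
    def test_labeling_annual_cost(self, cfg):
        scen = _scenario(policy=20_000 * 1_000)
        cost = annual_intervention_cost(scen, cfg.economics, 10)
        # 2 x 20 M GBP / 10 yr / 0.783 GBP-per-USD
        assert cost == pytest.approx(5_108_557, abs=1)

    def test_mandatory_worst_policy_cost_component(self, cfg):
        assert cfg.scenario("mandatory_worst").policy_cost_gbp == 500_000_000

    def test_zero_costs(self, cfg):
        assert annual_intervention_cost(_scenario(), cfg.economics, 10) == 0

    def test_scaling_and_horizon(self, cfg):
        scen = _scenario(policy=10_000_000)
        base = annual_intervention_cost(scen, cfg.economics, 10)
        assert annual_intervention_cost(scen, cfg.economics, 5) == pytest.approx(2 * base)


class TestUnitStateCosts:
    def test_baseline_unit_costs(self, cfg):
        units = unit_state_costs(cfg.economics, initial_state(cfg.epidemiology))
        assert units.acute_usd_per_person_year == pytest.approx(22_757, abs=1)
        assert units.chronic_usd_per_person_year == pytest.approx(1_401.4, abs=0.1)

    def test_linearity_in_expenditure(self, cfg):
        s0 = initial_state(cfg.epidemiology)
        units = unit_state_costs(cfg.economics, s0)
        cfg.economics.inpatient_expenditure_usd *= 2
        cfg.economics.outpatient_expenditure_usd *= 2
        doubled = unit_state_costs(cfg.economics, s0)
        assert doubled.acute_usd_per_person_year == pytest.approx(
            2 * units.acute_usd_per_person_year
        )

    def test_zero_occupancy_rejected(self, cfg):
        with pytest.raises(ValueError, match="occupanc"):
            unit_state_costs(cfg.economics, StateVector(1.0, 0.0, 1.0, 0.0))


class TestBenefitStream:
    def test_identical_trajectories_give_zero(self, cfg):
        traj = run_cohort(cfg, None)
        units = unit_state_costs(cfg.economics, initial_state(cfg.epidemiology))
        bens = benefit_stream(traj, traj, units)
        assert np.all(bens["benefit"] == 0)

    def test_single_year_toy_attribution(self):
        units = UnitStateCosts(10.0, 5.0)
        mk = lambda acute: Trajectory(
            "t",
            (StateVector(100, 100, 50, 0, 0), StateVector(90, acute, 50, 0, 1)),
            (),
        )
        bens = benefit_stream(mk(100), mk(90), units)
        assert bens["benefit"].iloc[0] == pytest.approx(100)
        assert bens["benefit_acute"].iloc[0] == pytest.approx(100)
        assert bens["benefit_chronic"].iloc[0] == pytest.approx(0)

    def test_mandatory_benefits_nondecreasing(self, cfg):
        null = run_cohort(cfg, None)
        scen = run_cohort(cfg, cfg.scenario("mandatory_best"))
        units = unit_state_costs(cfg.economics, initial_state(cfg.epidemiology))
        bens = benefit_stream(null, scen, units)["benefit"].to_numpy()
        assert np.all(np.diff(bens) >= 0)

    def test_mismatched_horizons_rejected(self, cfg):
        null = run_cohort(cfg, None)
        cfg.horizon_years = 5
        short = run_cohort(cfg, None)
        units = UnitStateCosts(1.0, 1.0)
        with pytest.raises(ValueError, match="horizon"):
            benefit_stream(null, short, units)


class TestDiscounting:
    def test_zero_rate_is_identity(self):
        stream = np.array([3.0, 1.0, 4.0])
        np.testing.assert_array_equal(discount_stream(stream, 0.0), stream)

    def test_unit_stream_geometric_sum(self):
        total = discount_stream(np.ones(10), 0.02).sum()
        assert total == pytest.approx(8.9826, abs=5e-4)

    def test_single_payment_one_step(self):
        assert discount_stream(np.array([102.0]), 0.02)[0] == pytest.approx(100.0)

    def test_begin_of_cycle_convention(self):
        disc = discount_stream(np.ones(3), 0.02, convention="begin")
        np.testing.assert_allclose(disc, [1.0, 1 / 1.02, 1 / 1.02**2])


class TestCumulativeNetBenefit:
    def test_zero_effect_zero_cost_is_all_zero(self, cfg):
        nb = cumulative_net_benefit(cfg, _scenario())
        assert nb.cumulative_cost == 0
        assert nb.cumulative_benefit == 0
        assert nb.cumulative_net_benefit == 0

    def test_zero_effect_positive_cost(self, cfg):
        scen = _scenario(monitoring=10_000_000)
        nb = cumulative_net_benefit(cfg, scen)
        annual = annual_intervention_cost(scen, cfg.economics, cfg.horizon_years)
        expected = -(annual * discount_stream(np.ones(10), 0.02)).sum()
        assert nb.cumulative_net_benefit == pytest.approx(expected, rel=1e-12)

    def test_net_equals_benefit_minus_cost_each_year(self, cfg):
        nb = cumulative_net_benefit(cfg, cfg.scenario("voluntary"))
        t = nb.table
        np.testing.assert_allclose(
            t["disc_net_benefit"], t["disc_benefit"] - t["disc_cost"], rtol=1e-12
        )
        np.testing.assert_allclose(
            t["cum_net_benefit"], np.cumsum(t["disc_net_benefit"]), rtol=1e-12
        )

    def test_benefit_ordering_across_policies(self, cfg):
        benefit = {
            name: cumulative_net_benefit(cfg, cfg.scenario(name)).cumulative_benefit
            for name in cfg.scenario_names
        }
        assert benefit["mandatory_best"] > benefit["voluntary"]
        assert benefit["voluntary"] > benefit["media_campaign"]
        assert benefit["media_campaign"] == pytest.approx(
            benefit["labeling"], rel=1e-12
        )

    def test_benefit_monotone_in_effect_size(self, cfg):
        outcomes = []
        for pct in (0, 5, 10, 20):
            outcomes.append(
                cumulative_net_benefit(cfg, _scenario(pct=pct)).cumulative_benefit
            )
        assert outcomes == sorted(outcomes)

    def test_mandatory_best_and_worst_differ_only_in_cost(self, cfg):
        best = cumulative_net_benefit(cfg, cfg.scenario("mandatory_best"))
        worst = cumulative_net_benefit(cfg, cfg.scenario("mandatory_worst"))
        np.testing.assert_allclose(
            best.table["benefit"], worst.table["benefit"], rtol=1e-12
        )
        assert worst.cumulative_cost > best.cumulative_cost

    def test_net_benefit_decreasing_in_discount_rate(self, cfg):
        outcomes = []
        for rate in (0.0, 0.02, 0.04):
            cfg.economics.discount_rate = rate
            outcomes.append(
                cumulative_net_benefit(
                    cfg, cfg.scenario("mandatory_best")
                ).cumulative_net_benefit
            )
        assert outcomes[0] > outcomes[1] > outcomes[2]

    def test_zero_rate_matches_nominal_sums(self, cfg):
        cfg.economics.discount_rate = 0.0
        nb = cumulative_net_benefit(cfg, cfg.scenario("voluntary"))
        assert nb.cumulative_benefit == pytest.approx(
            float(nb.table["benefit"].sum()), rel=1e-12
        )
        assert nb.cumulative_cost == pytest.approx(
            float(nb.table["cost"].sum()), rel=1e-12
        )

    def test_state_shares_sum_to_one(self, cfg):
        nb = cumulative_net_benefit(cfg, cfg.scenario("voluntary"))
        shares = nb.benefit_state_shares()
        assert shares["acute"] + shares["chronic"] == pytest.approx(1.0)
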