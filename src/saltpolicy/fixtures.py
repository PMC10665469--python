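"""Synthetic parameter sets and an independent verification oracle.

``perturbed_configs`` draws jittered but invariant-respecting parameter
bundles so every pipeline stage can be exercised on inputs other than the
packaged defaults.  ``oracle_run`` recomputes a cohort trajectory with
explicit per-state scalar arithmetic, recomputing the policy multipliers from
first principles and sharing no matrix code with the engine; agreement
between the two implementations is the central correctness property of the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig, PolicyScenario, ValueCI, validate_config
from .markov import StateVector, Trajectory

# numeric leaves subject to multiplicative jitter (ValueCI leaves jitter the
# point and both bounds by the same factor, preserving containment)
_JITTER_PATHS = (
    ("epidemiology", "total_deaths"),
    ("epidemiology", "mean_salt_intake"),
    ("epidemiology", "cvd_incidence"),
    ("epidemiology", "cvd_prevalence"),
    ("epidemiology", "cvd_mortality"),
    ("epidemiology", "acute_case_fatality"),
    ("epidemiology", "chronic_recurrence"),
    ("relative_risks", "incidence_pct_per_g_sodium"),
    ("relative_risks", "mortality_pct_per_10mmol_sodium"),
    ("economics", "inpatient_expenditure_usd"),
    ("economics", "outpatient_expenditure_usd"),
)


@dataclass(frozen=True)
class PerturbationSpec:
    """Uniform multiplicative jitter: each leaf is scaled by U(1-s, 1+s)."""

    seed: int
    n_sets: int = 10
    relative_scale: float = 0.2
    max_retries: int = 200
    bounds: dict = field(default_factory=dict)  # path -> (lo, hi) clamp

    def __post_init__(self):
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.relative_scale < 0:
            raise ValueError("relative_scale must be >= 0")


class GenerationError(RuntimeError):
    pass


def _jitter_one(base: ModelConfig, rng: np.random.Generator, spec: PerturbationSpec) -> ModelConfig:
    cfg = base.model_copy(deep=True)
    s = spec.relative_scale

    def factor() -> float:
        return float(rng.uniform(1.0 - s, 1.0 + s))

    for section, leaf in _JITTER_PATHS:
        parent = getattr(cfg, section)
        current = getattr(parent, leaf)
        f = factor()
        if isinstance(current, ValueCI):
            setattr(
                parent,
                leaf,
                ValueCI(point=current.point * f, low=current.low * f, high=current.high * f),
            )
        else:
            value = current * f
            lo, hi = spec.bounds.get(f"{section}.{leaf}", (None, None))
            if lo is not None:
                value = max(value, lo)
            if hi is not None:
                value = min(value, hi)
            setattr(parent, leaf, value)
    for scen in cfg.scenarios:
        f = factor()
        eff = scen.ten_year_salt_reduction_pct
        scen.ten_year_salt_reduction_pct = ValueCI(
            point=min(eff.point * f, 99.0),
            low=min(eff.low * f, 99.0),
            high=min(eff.high * f, 99.0),
        )
        scen.policy_cost_gbp *= factor()
        scen.monitoring_cost_gbp *= factor()
    return cfg


def perturbed_configs(base: ModelConfig, spec: PerturbationSpec) -> list[ModelConfig]:
    """Draw ``n_sets`` valid configs; identical seeds give identical output.

    Invalid draws (e.g. prevalence falling below incidence) are resampled up
    to ``max_retries`` times per set.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[ModelConfig] = []
    for _ in range(spec.n_sets):
        last_violations: list[str] = []
        for _ in range(spec.max_retries):
            cfg = _jitter_one(base, rng, spec)
            last_violations = validate_config(cfg)
            if not last_violations:
                out.append(cfg)
                break
        else:
            raise GenerationError(
                "retry budget exhausted; binding constraint(s): "
                + "; ".join(last_violations)
            )
    return out


def oracle_run(cfg: ModelConfig, scenario: PolicyScenario | None = None) -> Trajectory:
    """Brute-force scalar reimplementation of the cohort simulation.

    Deliberately written with per-state arithmetic and inline multiplier
    formulas (molar masses, linear/log-linear percent scaling, diagonal
    remainders) so that it cannot share a defect with the vectorised engine.
    """
    epi = cfg.epidemiology
    rr = cfg.relative_risks
    st = cfg.settings
    horizon = cfg.horizon_years

    pop = epi.total_population
    acute0 = epi.cvd_incidence.point / 100000.0 * pop
    chronic0 = (epi.cvd_prevalence.point - epi.cvd_incidence.point) / 100000.0 * pop
    h, a, c, d = pop - acute0 - chronic0, acute0, chronic0, 0.0

    p_other = (epi.total_deaths - epi.cvd_mortality.point / 100000.0 * pop) / pop
    if p_other < 0:
        raise ValueError("non-CVD death probability negative")

    states = [StateVector(h, a, c, d, cycle=0)]
    if scenario is None:
        rate = 0.0
        salt0 = epi.mean_salt_intake
    else:
        rate = scenario.ten_year_salt_reduction_pct.point / horizon
        salt0 = epi.mean_salt_intake

    for t in range(1, horizon + 1):
        dsalt = min(salt0 * rate / 100.0 * t, salt0)
        dna = dsalt * 22.99 / 58.44
        dmmol = dna * 1000.0 / 22.99
        if st.rr_composition == "linear":
            m_inc = 1.0 - rr.incidence_pct_per_g_sodium.point / 100.0 * dna
            m_mort = 1.0 - rr.mortality_pct_per_10mmol_sodium.point / 100.0 * dmmol / 10.0
            if m_inc <= 0 or m_mort <= 0:
                raise ValueError("multiplier <= 0")
        else:
            m_inc = np.exp(-rr.incidence_pct_per_g_sodium.point / 100.0 * dna)
            m_mort = np.exp(
                -rr.mortality_pct_per_10mmol_sodium.point / 100.0 * dmmol / 10.0
            )
        m_inc = max(m_inc, st.multiplier_floor)
        m_mort = max(m_mort, st.multiplier_floor)

        p_ha = epi.cvd_incidence.point / 100000.0 * m_inc
        p_ad = epi.acute_case_fatality * m_mort
        p_ca = epi.chronic_recurrence * m_inc

        h2 = h * (1.0 - p_ha - p_other)
        a2 = h * p_ha + c * p_ca
        c2 = a * (1.0 - p_ad) + c * (1.0 - p_ca - p_other)
        d2 = d + h * p_other + a * p_ad + c * p_other
        h, a, c, d = h2, a2, c2, d2
        states.append(StateVector(h, a, c, d, cycle=t))

    name = scenario.name if scenario is not None else "null"
    return Trajectory(scenario=name, states=tuple(states), matrices=())
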