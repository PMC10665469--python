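"""Four-state annual Markov cohort engine.

States, in row/column order: healthy, acute CVD, chronic CVD, dead.  The
cohort is closed: no entrants, and the initial total is conserved at every
cycle.  Healthy people either suffer a first-ever acute CVD event, die of
non-CVD causes, or stay healthy; the acute state lasts exactly one cycle and
resolves to chronic (survival to discharge) or death; chronic patients may
recur (back to acute), die of non-CVD causes, or remain chronic; death is
absorbing and no state leads back to healthy.

Per-100,000 annual rates are used directly as annual probabilities; at the
magnitudes involved (<= 0.0135) the difference from a hazard-based
conversion is far below other model uncertainty.  Occupancies are continuous
person counts (cohort macro-simulation semantics), not rounded integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import effects
from .config import EpidemiologyParams, ModelConfig, PolicyScenario

STATES = ("healthy", "acute", "chronic", "dead")
_H, _A, _C, _D = range(4)


@dataclass(frozen=True)
class StateVector:
    """Occupancies of the four health states at one cycle, in persons."""

    healthy: float
    acute: float
    chronic: float
    dead: float
    cycle: int = 0

    @property
    def total(self) -> float:
        return self.healthy + self.acute + self.chronic + self.dead

    def as_array(self) -> np.ndarray:
        return np.array([self.healthy, self.acute, self.chronic, self.dead])

    def validate(self) -> None:
        if min(self.healthy, self.acute, self.chronic, self.dead) < 0:
            raise ValueError(f"negative occupancy at cycle {self.cycle}")


class TransitionMatrix:
    """4x4 row-stochastic annual transition probabilities.

    Structural zeros: healthy->chronic, acute->acute, acute->healthy,
    chronic->healthy; the dead row is absorbing.
    """

    def __init__(self, array: np.ndarray):
        a = np.asarray(array, dtype=float)
        if a.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4")
        if (a < -1e-15).any() or (a > 1 + 1e-15).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsums = a.sum(axis=1)
        if not np.allclose(rowsums, 1.0, rtol=0, atol=1e-12):
            bad = STATES[int(np.argmax(np.abs(rowsums - 1)))]
            raise ValueError(f"row {bad!r} does not sum to 1 (sum={rowsums})")
        if not np.array_equal(a[_D], [0, 0, 0, 1]):
            raise ValueError("dead state must be absorbing")
        self.array = a

    def __getitem__(self, key):
        return self.array[key]


def initial_state(epi: EpidemiologyParams) -> StateVector:
    """Split the cohort at baseline using CVD incidence and prevalence.

    The acute pool holds one year of incident cases; the chronic pool holds
    the remaining prevalent cases; everyone else starts healthy.
    """
    if epi.cvd_prevalence.point < epi.cvd_incidence.point:
        raise ValueError("cvd_prevalence must be >= cvd_incidence")
    pop = epi.total_population
    acute = epi.cvd_incidence.point / 100_000 * pop
    chronic = (epi.cvd_prevalence.point - epi.cvd_incidence.point) / 100_000 * pop
    healthy = pop - acute - chronic
    return StateVector(healthy=healthy, acute=acute, chronic=chronic, dead=0.0, cycle=0)


def non_cvd_death_probability(epi: EpidemiologyParams) -> float:
    """Annual probability of death from non-CVD causes.

    Applied equally in the healthy and chronic states (non-CVD mortality is
    assumed independent of CVD history).
    """
    cvd_deaths = epi.cvd_mortality.point / 100_000 * epi.total_population
    other = epi.total_deaths - cvd_deaths
    if other < 0:
        raise ValueError(
            "total_deaths below CVD-attributed deaths: non-CVD death "
            "probability would be negative"
        )
    return other / epi.total_population


def build_transition_matrix(
    epi: EpidemiologyParams,
    incidence_multiplier: float = 1.0,
    mortality_multiplier: float = 1.0,
) -> TransitionMatrix:
    """Assemble the annual matrix, scaling CVD flows by policy multipliers.

    The incidence multiplier scales both first-ever (healthy->acute) and
    recurrent (chronic->acute) events; the mortality multiplier scales acute
    case fatality.  Diagonals absorb the row remainders.
    """
    for name, m in (
        ("incidence", incidence_multiplier),
        ("mortality", mortality_multiplier),
    ):
        if not 0 <= m <= 1:
            raise ValueError(f"{name} multiplier {m} outside [0, 1]")

    p_other = non_cvd_death_probability(epi)
    p_ha = epi.cvd_incidence.point / 100_000 * incidence_multiplier
    p_ad = epi.acute_case_fatality * mortality_multiplier
    p_ca = epi.chronic_recurrence * incidence_multiplier

    m = np.zeros((4, 4))
    m[_H, _A] = p_ha
    m[_H, _D] = p_other
    m[_H, _H] = 1.0 - p_ha - p_other
    m[_A, _D] = p_ad
    m[_A, _C] = 1.0 - p_ad
    m[_C, _A] = p_ca
    m[_C, _D] = p_other
    m[_C, _C] = 1.0 - p_ca - p_other
    m[_D, _D] = 1.0
    for i, state in enumerate(STATES):
        if m[i, i] < 0:
            raise ValueError(f"row {state!r}: probabilities exceed 1")
    return TransitionMatrix(m)


def step(state: StateVector, matrix: TransitionMatrix) -> StateVector:
    """Advance the cohort one annual cycle (left-multiply by the matrix)."""
    nxt = state.as_array() @ matrix.array
    return StateVector(
        healthy=float(nxt[_H]),
        acute=float(nxt[_A]),
        chronic=float(nxt[_C]),
        dead=float(nxt[_D]),
        cycle=state.cycle + 1,
    )


@dataclass(frozen=True)
class Trajectory:
    """State vectors for cycles 0..horizon plus the matrices that drove them."""

    scenario: str
    states: tuple[StateVector, ...]
    matrices: tuple[TransitionMatrix, ...]  # matrices[t-1] drove cycle t-1 -> t

    def __len__(self) -> int:
        return len(self.states)

    @property
    def horizon(self) -> int:
        return len(self.states) - 1

    @property
    def initial_total(self) -> float:
        return self.states[0].total

    def occupancy(self, state: str) -> np.ndarray:
        return np.array([getattr(s, state) for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": [s.cycle for s in self.states],
                **{name: self.occupancy(name) for name in STATES},
                "scenario": self.scenario,
            }
        )


def run_cohort(cfg: ModelConfig, scenario: PolicyScenario | None = None) -> Trajectory:
    """Run the closed-cohort simulation for one policy (or the null baseline).

    The transition matrix is rebuilt every cycle with that year's risk
    multipliers from the policy's effect trajectory; the null scenario keeps
    both multipliers at 1 throughout.
    """
    epi = cfg.epidemiology
    horizon = cfg.horizon_years
    eff = effects.effect_trajectory(
        scenario,
        epi,
        cfg.relative_risks,
        horizon,
        composition=cfg.settings.rr_composition,
        floor=cfg.settings.multiplier_floor,
    )
    states = [initial_state(epi)]
    matrices = []
    for t in range(1, horizon + 1):
        m = build_transition_matrix(
            epi,
            incidence_multiplier=float(eff.incidence_multiplier[t]),
            mortality_multiplier=float(eff.mortality_multiplier[t]),
        )
        matrices.append(m)
        states.append(step(states[-1], m))
    name = scenario.name if scenario is not None else "null"
    return Trajectory(scenario=name, states=tuple(states), matrices=tuple(matrices))
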