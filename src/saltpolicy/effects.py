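"""Policy effect trajectories: salt decline and risk multipliers.

Each policy is characterised by the percentage of baseline salt intake it
removes over a decade.  Assuming intake falls at a constant annual rate, the
cumulative reduction in year ``t`` is linear in ``t``.  The reduction is
converted from salt (NaCl) to sodium by molar-mass ratio and mapped to
multiplicative scalings of CVD incidence and mortality through the relative
risks (percent change per 1 g/day sodium for incidence, per 10 mmol/day
sodium for mortality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EpidemiologyParams, PolicyScenario, RelativeRiskParams

NA_MOLAR_MASS = 22.99  # g/mol
NACL_MOLAR_MASS = 58.44  # g/mol
SODIUM_MASS_FRACTION = NA_MOLAR_MASS / NACL_MOLAR_MASS  # ~0.39339 g Na per g NaCl


def annual_reduction_rate(ten_year_pct: float, duration_years: int) -> float:
    """Annual salt-reduction rate, in percentage points of baseline per year.

    A decade effect of 2/15/20 % over 10 years gives 0.2/1.5/2.0 %/yr.
    """
    if duration_years < 1:
        raise ValueError("duration_years must be >= 1")
    if not 0 <= ten_year_pct < 100:
        raise ValueError("ten_year_pct must be in [0, 100)")
    return ten_year_pct / duration_years


def cumulative_salt_reduction(
    baseline_salt: float, rate_pct_per_year: float, year: int
) -> float:
    """Cumulative salt reduction (g NaCl/day) achieved by ``year``.

    Linear in time and capped so that intake never becomes negative.
    """
    if year < 0:
        raise ValueError("year must be >= 0")
    return min(baseline_salt * rate_pct_per_year / 100.0 * year, baseline_salt)


def salt_to_sodium(salt_g: float) -> float:
    """Convert g NaCl/day to g Na/day (mass fraction 22.99/58.44)."""
    if salt_g < 0:
        raise ValueError("salt mass must be non-negative")
    return salt_g * SODIUM_MASS_FRACTION


def sodium_to_mmol(sodium_g: float) -> float:
    """Convert g Na/day to mmol Na/day (1 mmol Na = 22.99 mg)."""
    if sodium_g < 0:
        raise ValueError("sodium mass must be non-negative")
    return sodium_g * 1000.0 / NA_MOLAR_MASS


def incidence_multiplier(
    delta_sodium_g: float,
    rr: RelativeRiskParams,
    *,
    composition: str = "linear",
    floor: float = 0.05,
) -> float:
    """Scaling applied to CVD incidence for a sodium reduction of ``delta``.

    Linear composition: ``1 - (pct/100) * delta``; log-linear:
    ``exp(-(pct/100) * delta)``.  Values are clamped at ``floor`` and a
    non-positive linear multiplier is a domain error (effect too large for
    the linear form).
    """
    if delta_sodium_g < 0:
        raise ValueError("sodium reduction must be non-negative")
    pct = rr.incidence_pct_per_g_sodium.point
    return _compose(pct / 100.0 * delta_sodium_g, composition, floor, "incidence")


def mortality_multiplier(
    delta_sodium_g: float,
    rr: RelativeRiskParams,
    *,
    composition: str = "linear",
    floor: float = 0.05,
) -> float:
    """Scaling applied to CVD case fatality for a sodium reduction of ``delta``."""
    if delta_sodium_g < 0:
        raise ValueError("sodium reduction must be non-negative")
    pct = rr.mortality_pct_per_10mmol_sodium.point
    effect = pct / 100.0 * sodium_to_mmol(delta_sodium_g) / 10.0
    return _compose(effect, composition, floor, "mortality")


def _compose(effect: float, composition: str, floor: float, label: str) -> float:
    if composition == "linear":
        mult = 1.0 - effect
        if mult <= 0:
            raise ValueError(
                f"{label} multiplier {mult:.4f} <= 0: effect too large for the "
                "linear composition; use loglinear"
            )
    elif composition == "loglinear":
        mult = math.exp(-effect)
    else:
        raise ValueError(f"unknown rr composition {composition!r}")
    return max(mult, floor)


@dataclass(frozen=True)
class EffectTrajectory:
    """Per-year cumulative reductions and risk multipliers for one policy.

    Index 0 is baseline (zero reduction, multipliers 1); index ``t`` carries
    the effect in force during cycle ``t``.
    """

    scenario: str
    salt_reduction_g: np.ndarray
    sodium_reduction_g: np.ndarray
    sodium_reduction_mmol: np.ndarray
    incidence_multiplier: np.ndarray
    mortality_multiplier: np.ndarray

    def __len__(self) -> int:
        return len(self.salt_reduction_g)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": np.arange(len(self)),
                "salt_reduction_g": self.salt_reduction_g,
                "sodium_reduction_g": self.sodium_reduction_g,
                "sodium_reduction_mmol": self.sodium_reduction_mmol,
                "incidence_multiplier": self.incidence_multiplier,
                "mortality_multiplier": self.mortality_multiplier,
            }
        )


def effect_trajectory(
    scenario: PolicyScenario | None,
    epi: EpidemiologyParams,
    rr: RelativeRiskParams,
    horizon: int,
    *,
    composition: str = "linear",
    floor: float = 0.05,
) -> EffectTrajectory:
    """Compose the yearly effect chain for one policy over the horizon.

    Each year's reduction takes full effect within that year (no phase-in).
    A ``None`` scenario is the null (no-intervention) trajectory.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    years = np.arange(horizon + 1)
    if scenario is None:
        zeros = np.zeros(horizon + 1)
        return EffectTrajectory("null", zeros, zeros.copy(), zeros.copy(),
                                np.ones(horizon + 1), np.ones(horizon + 1))

    rate = annual_reduction_rate(
        scenario.ten_year_salt_reduction_pct.point, horizon
    )
    salt = np.array(
        [cumulative_salt_reduction(epi.mean_salt_intake, rate, int(t)) for t in years]
    )
    sodium = np.array([salt_to_sodium(s) for s in salt])
    mmol = np.array([sodium_to_mmol(s) for s in sodium])
    inc = np.array(
        [incidence_multiplier(s, rr, composition=composition, floor=floor) for s in sodium]
    )
    mort = np.array(
        [mortality_multiplier(s, rr, composition=composition, floor=floor) for s in sodium]
    )
    return EffectTrajectory(scenario.name, salt, sodium, mmol, inc, mort)
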