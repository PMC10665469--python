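"""Deterministic one-way sensitivity analysis (tornado ranking).

Each sweep sets a single parameter to its low and high bound, holding every
other parameter at its point estimate, and records the cumulative net benefit
over the horizon.  Sweeps are ranked by outcome range width, widest first.
Default sweep bounds are the published uncertainty intervals plus the 0-4%
discount-rate range.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import pandas as pd

from .config import ConfigValidationError, ModelConfig, ValueCI, validate_config
from .economics import cumulative_net_benefit


@dataclass(frozen=True)
class SweepSpec:
    """One parameter sweep: dotted path into the config, low/high bounds."""

    path: str
    low: float
    high: float
    label: str

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError(f"{self.label}: low {self.low} > high {self.high}")


@dataclass(frozen=True)
class SensitivityResult:
    label: str
    path: str
    low: float
    high: float
    nb_low: float
    nb_high: float
    nb_point: float

    @property
    def width(self) -> float:
        return abs(self.nb_high - self.nb_low)


def _resolve_parent(cfg: ModelConfig, path: str):
    """Walk a dotted path; return (parent object, final attribute name).

    Scenarios are addressed by name: ``scenarios.<name>.<field>``.
    """
    parts = path.split(".")
    if len(parts) < 2:
        raise KeyError(f"config path {path!r}: expected a dotted path")
    node = cfg
    i = 0
    while i < len(parts) - 1:
        part = parts[i]
        if part == "scenarios":
            if i + 1 >= len(parts) - 1:
                raise KeyError(f"config path {path!r}: scenario field missing")
            node = node.scenario(parts[i + 1])
            i += 2
            continue
        if not hasattr(node, part):
            raise KeyError(f"config path {path!r}: no field {part!r}")
        node = getattr(node, part)
        i += 1
    return node, parts[-1]


def set_parameter(cfg: ModelConfig, path: str, value: float) -> ModelConfig:
    """Return a deep copy of ``cfg`` with one parameter replaced.

    A path ending at a point-with-bounds parameter sets its point estimate.
    """
    out = cfg.model_copy(deep=True)
    parent, leaf = _resolve_parent(out, path)
    if not hasattr(parent, leaf):
        raise KeyError(f"config path {path!r}: no field {leaf!r}")
    current = getattr(parent, leaf)
    if isinstance(current, ValueCI):
        # widen bounds if the swept value escapes them, keeping the CI valid
        setattr(
            parent,
            leaf,
            ValueCI(
                point=value,
                low=min(current.low, value),
                high=max(current.high, value),
            ),
        )
    else:
        setattr(parent, leaf, type(current)(value) if current is not None else value)
    return out


def one_way(
    cfg: ModelConfig, scenario_name: str, spec: SweepSpec
) -> SensitivityResult:
    """Re-run the model with one parameter at its low, then high, bound."""
    outcomes = {}
    for bound, value in (("low", spec.low), ("high", spec.high)):
        swept = set_parameter(cfg, spec.path, value)
        violations = validate_config(swept)
        if violations:
            raise ConfigValidationError(
                [f"sweep {spec.label!r} at {bound}={value}: {v}" for v in violations]
            )
        outcomes[bound] = cumulative_net_benefit(
            swept, swept.scenario(scenario_name)
        ).cumulative_net_benefit
    nb_point = cumulative_net_benefit(
        cfg, cfg.scenario(scenario_name)
    ).cumulative_net_benefit
    return SensitivityResult(
        label=spec.label,
        path=spec.path,
        low=spec.low,
        high=spec.high,
        nb_low=outcomes["low"],
        nb_high=outcomes["high"],
        nb_point=nb_point,
    )


def default_sweeps(cfg: ModelConfig, scenario_name: str) -> list[SweepSpec]:
    """The standard sweep set: discount 0-4%, policy effect range, CVD
    incidence/prevalence/mortality intervals, relative-risk intervals."""
    scen = cfg.scenario(scenario_name)
    epi = cfg.epidemiology
    rr = cfg.relative_risks
    eff = scen.ten_year_salt_reduction_pct
    return [
        SweepSpec("economics.discount_rate", 0.0, 0.04, "Discount rate"),
        SweepSpec(
            f"scenarios.{scenario_name}.ten_year_salt_reduction_pct",
            eff.low,
            eff.high,
            "Policy effect on salt intake",
        ),
        SweepSpec(
            "epidemiology.cvd_incidence",
            epi.cvd_incidence.low,
            epi.cvd_incidence.high,
            "CVD incidence",
        ),
        SweepSpec(
            "epidemiology.cvd_prevalence",
            epi.cvd_prevalence.low,
            epi.cvd_prevalence.high,
            "CVD prevalence",
        ),
        SweepSpec(
            "epidemiology.cvd_mortality",
            epi.cvd_mortality.low,
            epi.cvd_mortality.high,
            "CVD mortality",
        ),
        SweepSpec(
            "relative_risks.incidence_pct_per_g_sodium",
            rr.incidence_pct_per_g_sodium.low,
            rr.incidence_pct_per_g_sodium.high,
            "RR for CVD incidence",
        ),
        SweepSpec(
            "relative_risks.mortality_pct_per_10mmol_sodium",
            rr.mortality_pct_per_10mmol_sodium.low,
            rr.mortality_pct_per_10mmol_sodium.high,
            "RR for CVD mortality",
        ),
    ]


def tornado(
    cfg: ModelConfig, scenario_name: str, specs: list[SweepSpec] | None = None
) -> pd.DataFrame:
    """Run every sweep and rank results by descending outcome range width."""
    if specs is None:
        specs = default_sweeps(cfg, scenario_name)
    if not specs:
        raise ValueError("no sweep specs")
    results = [one_way(cfg, scenario_name, spec) for spec in specs]
    frame = pd.DataFrame(
        {
            "label": [r.label for r in results],
            "low_value": [r.low for r in results],
            "high_value": [r.high for r in results],
            "nb_low": [r.nb_low for r in results],
            "nb_high": [r.nb_high for r in results],
            "nb_point": [r.nb_point for r in results],
            "width": [r.width for r in results],
        }
    )
    return frame.sort_values("width", ascending=False, kind="stable").reset_index(
        drop=True
    )
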