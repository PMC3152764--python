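"""One-way (tornado) and two-way sensitivity analyses.

Every run in an analysis shares the master seed and the per-purpose substream
keying, so a parameter change perturbs only the draws it logically touches
(common random numbers).  Tornado bars therefore rank parameters by genuine
output range, not by Monte Carlo noise, even at desk-scale cohort sizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Sequence

import pandas as pd

from .engine import SimulationConfig, simulate_cohort
from .outcomes import CohortComparison, compare_result
from .treatment import PERSISTENCE_PRESETS

__all__ = [
    "SensitivitySpec",
    "DEFAULT_TORNADO",
    "set_param",
    "run_scenario",
    "run_tornado",
    "run_two_way",
    "two_way_reference_config",
]

_OUTCOME_FIELDS = [f.name for f in dataclasses.fields(CohortComparison)]


def set_param(config: SimulationConfig, name: str, value: Any) -> SimulationConfig:
    """Return a copy of ``config`` with the dotted parameter set.

    Special values: ``treatment.persistence`` accepts a preset name;
    ``test.rescreen_interval`` accepts ``"once"`` for a single screen.
    """
    if name == "treatment.persistence" and isinstance(value, str):
        try:
            value = PERSISTENCE_PRESETS[value]
        except KeyError:
            raise KeyError(
                f"unknown persistence preset {value!r}; "
                f"choose from {sorted(PERSISTENCE_PRESETS)}"
            ) from None
    if name == "test.rescreen_interval" and value == "once":
        value = None

    parts = name.split(".")
    objs = [config]
    for p in parts[:-1]:
        if not hasattr(objs[-1], p):
            raise KeyError(f"unresolvable parameter {name!r}")
        objs.append(getattr(objs[-1], p))
    if not hasattr(objs[-1], parts[-1]):
        raise KeyError(f"unresolvable parameter {name!r}")
    updated = dataclasses.replace(objs[-1], **{parts[-1]: value})
    for obj, attr in zip(reversed(objs[:-1]), reversed(parts[:-1])):
        updated = dataclasses.replace(obj, **{attr: updated})
    return updated


def run_scenario(config: SimulationConfig) -> CohortComparison:
    """One paired cohort run reduced to its comparison statistics."""
    return compare_result(simulate_cohort(config))


@dataclass(frozen=True)
class SensitivitySpec:
    """One-way plan: ``(parameter, low, high)`` triples; for categorical
    parameters (persistence pattern, rescreen interval) low/high are the two
    scenario values rather than numeric bounds.  ``outcome`` picks the
    comparison field whose range orders the tornado."""

    one_way: tuple[tuple[str, Any, Any], ...]
    outcome: str = "ad_free_years_incremental"

    def __post_init__(self) -> None:
        if self.outcome not in _OUTCOME_FIELDS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        for name, lo, hi in self.one_way:
            if (
                isinstance(lo, (int, float))
                and isinstance(hi, (int, float))
                and lo > hi
            ):
                raise ValueError(f"low > high for {name!r}")


#: Default one-way plan over the five varied inputs.  Extremes stated with
#: the base case (screen age 50-80, duration of sensitivity up to 25 y) are
#: used where available; the remaining ranges are package defaults, not
#: published values.
DEFAULT_TORNADO = SensitivitySpec(
    one_way=(
        ("treatment.effectiveness", 0.25, 0.75),
        ("test.first_screen_age", 50.0, 80.0),
        ("test.rescreen_interval", "once", 5.0),
        ("test.duration_of_sensitivity", 5.0, 25.0),
        ("treatment.persistence", "ad_ci_model_1", "unending"),
    )
)


def run_tornado(spec: SensitivitySpec, config: SimulationConfig) -> pd.DataFrame:
    """Vary each parameter alone (others at base, common seed); one row per
    parameter with low/high values for every outcome, sorted by descending
    range of ``spec.outcome``."""
    rows = []
    for name, lo, hi in spec.one_way:
        row: dict[str, Any] = {"parameter": name, "low": lo, "high": hi}
        for tag, value in (("low", lo), ("high", hi)):
            cmp = run_scenario(set_param(config, name, value))
            for f in _OUTCOME_FIELDS:
                row[f"{f}_{tag}"] = getattr(cmp, f)
        base_lo = row[f"{spec.outcome}_low"]
        base_hi = row[f"{spec.outcome}_high"]
        if base_lo is None or base_hi is None:
            row["range"] = float("nan")
        else:
            row["range"] = abs(base_hi - base_lo)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("range", ascending=False, ignore_index=True)
    return df


def two_way_reference_config(config: SimulationConfig) -> SimulationConfig:
    """Scenario backdrop for the sensitivity × specificity surface: 15-year
    duration of sensitivity with 5-yearly rescreening from the first-screen
    age (the published surface screens repeatedly from age 70; the interval
    itself is not printed — 5 years is this package's reconstruction)."""
    cfg = set_param(config, "test.duration_of_sensitivity", 15.0)
    return set_param(cfg, "test.rescreen_interval", 5.0)


def run_two_way(
    config: SimulationConfig,
    sensitivities: Sequence[float],
    specificities: Sequence[float],
    outcome_scale: float = 100_000.0,
) -> pd.DataFrame:
    """AD cases avoided per ``outcome_scale`` screened over a sensitivity ×
    specificity grid (rows: specificity, columns: sensitivity); one paired
    run per cell under common seeds."""
    mat = []
    for sp in specificities:
        row = []
        for se in sensitivities:
            cfg = set_param(config, "test.sensitivity", float(se))
            cfg = set_param(cfg, "test.specificity", float(sp))
            res = simulate_cohort(cfg)
            row.append(res.cases_avoided * outcome_scale / cfg.cohort_size)
        mat.append(row)
    return pd.DataFrame(
        mat,
        index=pd.Index(specificities, name="specificity"),
        columns=pd.Index(sensitivities, name="sensitivity"),
    )
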