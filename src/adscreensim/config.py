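"""Scenario configuration as structured text (YAML).

Every base-case parameter is nameable in one file; the incidence table and
the mortality fixture spec can be inlined, and a life table can alternatively
be pulled from a delimited-text file next to the scenario.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .engine import SimulationConfig
from .hazards import IncidenceSchedule
from .lifetables import (
    GompertzMakehamParams,
    LifeTable,
    MortalityFixtureSpec,
    read_life_table_csv,
)
from .screening import ScreeningTest
from .treatment import PERSISTENCE_PRESETS, PersistencePattern, TreatmentPlan

__all__ = ["config_to_dict", "config_from_dict", "load_scenario", "save_scenario", "config_hash"]


def _persistence_to_obj(p: PersistencePattern) -> Any:
    preset = PERSISTENCE_PRESETS.get(p.name)
    if preset == p:
        return p.name
    return {
        "name": p.name,
        "p_disc_first_6mo": p.p_disc_first_6mo,
        "p_disc_second_6mo": p.p_disc_second_6mo,
        "after_year_one": p.after_year_one,
    }


def _persistence_from_obj(obj: Any) -> PersistencePattern:
    if isinstance(obj, str):
        if obj not in PERSISTENCE_PRESETS:
            raise KeyError(f"unknown persistence preset {obj!r}")
        return PERSISTENCE_PRESETS[obj]
    return PersistencePattern(**obj)


def _mortality_to_obj(spec: MortalityFixtureSpec) -> dict:
    if spec.model == "tabular":
        t = spec.table
        assert t is not None
        return {
            "model": "tabular",
            "open_age": t.open_age,
            "ages": [int(a) for a in t.ages],
            "q_male": [float(q) for q in t.q_male],
            "q_female": [float(q) for q in t.q_female],
        }
    assert spec.parameters is not None and spec.calibration_target is not None
    return {
        "model": "gompertz_makeham",
        "age_lo": spec.age_lo,
        "open_age": spec.open_age,
        "parameters": {
            sex: dataclasses.asdict(spec.parameters[sex]) for sex in ("male", "female")
        },
        "calibration_target": dict(spec.calibration_target),
    }


def _mortality_from_obj(obj: Mapping, base_dir: Path | None) -> MortalityFixtureSpec:
    model = obj.get("model", "gompertz_makeham")
    if model == "tabular":
        if "path" in obj:
            path = Path(obj["path"])
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            table = read_life_table_csv(path, open_age=obj.get("open_age"))
        else:
            table = LifeTable(
                ages=np.asarray(obj["ages"], dtype=float),
                q_male=np.asarray(obj["q_male"], dtype=float),
                q_female=np.asarray(obj["q_female"], dtype=float),
                open_age=float(obj.get("open_age", 100.0)),
            )
        return MortalityFixtureSpec(model="tabular", table=table, open_age=int(table.open_age))
    return MortalityFixtureSpec(
        model="gompertz_makeham",
        parameters={
            sex: GompertzMakehamParams(**obj["parameters"][sex]) for sex in ("male", "female")
        },
        calibration_target={sex: float(obj["calibration_target"][sex]) for sex in ("male", "female")},
        age_lo=int(obj.get("age_lo", 50)),
        open_age=int(obj.get("open_age", 100)),
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "cohort_size": config.cohort_size,
        "seed": config.seed,
        "pct_male": config.pct_male,
        "age_cap": config.age_cap,
        "discount_rate": config.discount_rate,
        "discounting_enabled": config.discounting_enabled,
        "hazard_method": config.hazard_method,
        "anchored_incidence": config.anchored_incidence,
        "count_adverse_events": config.count_adverse_events,
        "incidence": {
            "terminal_age": config.incidence.terminal_age,
            "anchor_ages": list(config.incidence.anchor_ages)
            if config.incidence.anchor_ages
            else None,
            "strata": [list(s) for s in config.incidence.strata],
        },
        "screening": {
            "sensitivity": config.test.sensitivity,
            "specificity": config.test.specificity,
            "duration_of_sensitivity": config.test.duration_of_sensitivity,
            "first_screen_age": config.test.first_screen_age,
            "rescreen_interval": config.test.rescreen_interval,
            "stop_age": config.test.stop_age,
            "age_cap": config.test.age_cap,
        },
        "treatment": {
            "effectiveness": config.treatment.effectiveness,
            "persistence": _persistence_to_obj(config.treatment.persistence),
            "ae_rates": [list(r) for r in config.treatment.ae_rates],
            "discontinue_on_ae": config.treatment.discontinue_on_ae,
            "ae_monitoring_interval_first_year": config.treatment.ae_monitoring_interval_first_year,
        },
        "mortality": _mortality_to_obj(config.mortality),
    }


def config_from_dict(d: Mapping, base_dir: Path | None = None) -> SimulationConfig:
    kwargs: dict[str, Any] = {}
    for key in (
        "cohort_size",
        "seed",
        "pct_male",
        "age_cap",
        "discount_rate",
        "discounting_enabled",
        "hazard_method",
        "anchored_incidence",
        "count_adverse_events",
    ):
        if key in d:
            kwargs[key] = d[key]
    if "incidence" in d:
        inc = d["incidence"]
        kwargs["incidence"] = IncidenceSchedule(
            strata=tuple(tuple(float(x) for x in s) for s in inc["strata"]),
            terminal_age=float(inc.get("terminal_age", 100.0)),
            anchor_ages=tuple(inc["anchor_ages"]) if inc.get("anchor_ages") else None,
        )
    if "screening" in d:
        kwargs["test"] = ScreeningTest(**d["screening"])
    if "treatment" in d:
        t = dict(d["treatment"])
        if "persistence" in t:
            t["persistence"] = _persistence_from_obj(t["persistence"])
        if "ae_rates" in t:
            t["ae_rates"] = tuple(tuple(float(x) for x in r) for r in t["ae_rates"])
        kwargs["treatment"] = TreatmentPlan(**t)
    if "mortality" in d:
        kwargs["mortality"] = _mortality_from_obj(d["mortality"], base_dir)
    return SimulationConfig(**kwargs)


def load_scenario(path: str | Path) -> SimulationConfig:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return config_from_dict(d or {}, base_dir=path.parent)


def save_scenario(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of the full scenario, for run logs."""
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
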