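"""Paired-arm time-to-event engine.

Each simulated patient is followed from the first-screen age until all-cause
death (or the age cap).  Sex, scheduled onset age, and death age are drawn
once per patient and reused in both the no-screening and screening arms
(common random numbers), so between-arm differences reflect only the
intervention.  Random draws come from per-purpose substreams keyed off the
master seed — changing, say, a test parameter leaves onset and death draws
untouched, which keeps sensitivity analyses quiet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .hazards import (
    DEFAULT_INCIDENCE,
    HazardFunction,
    IncidenceSchedule,
    Method,
    build_hazard,
    competing_event_probability,
    expected_min_event_time,
    invert_survival,
)
from .lifetables import (
    DEFAULT_FIXTURE_SPEC,
    LifeTable,
    MortalityFixtureSpec,
    death_hazard,
    generate_fixture,
)
from .screening import ScreeningTest, run_screening_policy, screen_ages
from .treatment import (
    TreatmentPlan,
    apply_progression_slowdown,
    sample_discontinuation_time,
    schedule_adverse_events,
    truncate_at_first_detected_ae,
)

__all__ = [
    "SimulationConfig",
    "PatientTrajectory",
    "ArmTotals",
    "CohortResult",
    "simulate_patient",
    "simulate_cohort",
    "analytic_ad_free_years",
    "analytic_case_probability",
]

# purpose codes for random substreams (seed spawn keys)
_SEX, _ONSET, _DEATH, _SCREEN, _PERS, _AE = range(6)
_U_EPS = 1e-15


@dataclass(frozen=True)
class SimulationConfig:
    """Every base-case parameter of the model in one place.

    The first-screen age lives on the screening test (it is the model entry
    age: AD-free years accrue from it).  Discounting at ``discount_rate`` is
    implemented but off by default; the headline per-1000 outcomes are
    undiscounted years.
    """

    cohort_size: int = 100_000
    seed: int = 1234
    pct_male: float = 0.46
    age_cap: float = 100.0
    discount_rate: float = 0.03
    discounting_enabled: bool = False
    incidence: IncidenceSchedule = DEFAULT_INCIDENCE
    mortality: MortalityFixtureSpec = DEFAULT_FIXTURE_SPEC
    test: ScreeningTest = field(default_factory=ScreeningTest)
    treatment: TreatmentPlan = field(default_factory=TreatmentPlan)
    hazard_method: Method = "piecewise_exponential"
    # the incidence curve "smooths" between stratum anchor ages by default —
    # the published model argues the smoother approximation is more realistic
    # between adjacent strata, and the base-case reproduction bears that out
    anchored_incidence: bool = True
    count_adverse_events: bool = True

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be at least 1")
        if not 0.0 <= self.pct_male <= 1.0:
            raise ValueError("pct_male must be in [0, 1]")
        if self.test.first_screen_age >= self.age_cap:
            raise ValueError("first screen must precede the age cap")
        if self.incidence.terminal_age != self.age_cap:
            raise ValueError("incidence terminal age must equal the age cap")

    @property
    def entry_age(self) -> float:
        return self.test.first_screen_age


@dataclass(frozen=True)
class PatientTrajectory:
    """One patient's course in one arm."""

    id: int
    sex: Literal["male", "female"]
    arm: Literal["no_screening", "screening"]
    scheduled_onset_age: float | None
    death_age: float
    first_positive_age: float | None = None
    treatment_start_age: float | None = None
    treatment_stop_age: float | None = None
    realized_onset_age: float | None = None
    ad_free_years: float = 0.0
    treatment_years: float = 0.0
    n_adverse_events: int = 0

    @property
    def is_case(self) -> bool:
        return self.realized_onset_age is not None


class _Context:
    """Per-run precomputation: hazards, life table, and uniform substreams."""

    def __init__(self, config: SimulationConfig, n: int):
        self.config = config
        self.table: LifeTable = generate_fixture(config.mortality)
        entry = config.entry_age
        self.onset_hz = {
            sex: build_hazard(
                config.incidence, sex, entry, config.hazard_method, config.anchored_incidence
            )
            for sex in ("male", "female")
        }
        self.death_hz = {sex: death_hazard(self.table, sex, entry) for sex in ("male", "female")}
        self.n_screens = sum(1 for _ in screen_ages(config.test))

        def stream(*key: int) -> np.ndarray:
            gen = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))
            return np.clip(gen.random(n), _U_EPS, 1.0 - _U_EPS)

        self.u_sex = stream(_SEX)
        self.u_onset = stream(_ONSET)
        self.u_death = stream(_DEATH)
        self.u_screen = np.column_stack([stream(_SCREEN, k) for k in range(self.n_screens)])
        self.u_pers = np.column_stack([stream(_PERS, j) for j in range(3)])
        self._seed = config.seed

        # vectorized inverse transforms, one per sex
        self.sex = np.where(self.u_sex < config.pct_male, "male", "female")
        self.onset_age = np.full(n, np.nan)
        self.death_age = np.full(n, np.nan)
        for sex in ("male", "female"):
            m = self.sex == sex
            if not m.any():
                continue
            t = invert_survival(self.onset_hz[sex], self.u_onset[m])
            self.onset_age[m] = entry + t
            td = invert_survival(self.death_hz[sex], self.u_death[m])
            td = np.where(np.isnan(td), self.table.open_age - entry, td)
            self.death_age[m] = np.minimum(entry + td, self.table.open_age)

    def ae_uniform_stream(self, pid: int):
        gen = np.random.default_rng(np.random.SeedSequence(self._seed, spawn_key=(_AE, pid)))
        while True:
            yield float(np.clip(gen.random(), _U_EPS, 1.0 - _U_EPS))


def _discount_years(a: float, b: float, entry: float, rate: float) -> float:
    """Present value at entry of one unit/year accrued over ages [a, b]."""
    if b <= a:
        return 0.0
    if rate <= 0:
        return b - a
    return (math.exp(-rate * (a - entry)) - math.exp(-rate * (b - entry))) / rate


def _years(a: float, b: float, cfg: SimulationConfig) -> float:
    if cfg.discounting_enabled:
        return _discount_years(a, b, cfg.entry_age, cfg.discount_rate)
    return max(0.0, b - a)


def _simulate_one(
    ctx: _Context, pid: int, screen_log: list[tuple] | None = None
) -> tuple[PatientTrajectory, PatientTrajectory]:
    cfg = ctx.config
    entry = cfg.entry_age
    cap = cfg.age_cap
    sex = str(ctx.sex[pid])
    onset = None if np.isnan(ctx.onset_age[pid]) else float(ctx.onset_age[pid])
    death = float(ctx.death_age[pid])

    def free_years(onset_age: float | None) -> float:
        end = min(death, cap) if onset_age is None else min(onset_age, death, cap)
        return _years(entry, end, cfg)

    def case(onset_age: float | None) -> float | None:
        """Realized onset: only an onset strictly before death and the cap
        counts as an AD case (ties go to death / the cap)."""
        if onset_age is not None and onset_age < death and onset_age < cap:
            return onset_age
        return None

    base = PatientTrajectory(
        id=pid,
        sex=sex,  # type: ignore[arg-type]
        arm="no_screening",
        scheduled_onset_age=onset,
        death_age=death,
        realized_onset_age=case(onset),
        ad_free_years=free_years(onset),
    )

    outcomes = [] if screen_log is not None else None
    first_pos = run_screening_policy(onset, death, cfg.test, ctx.u_screen[pid], outcomes)
    if screen_log is not None:
        screen_log.extend(
            (pid, o.screen_age, o.truth, o.result) for o in outcomes  # type: ignore[union-attr]
        )
    if first_pos is None:
        screen_traj = replace(base, arm="screening")
        return base, screen_traj

    plan = cfg.treatment
    u1, u2, u3 = ctx.u_pers[pid]
    disc = sample_discontinuation_time(plan.persistence, float(u1), float(u2), float(u3))

    ae_times: list[float] = []
    if plan.discontinue_on_ae:
        horizon = min(disc, death - first_pos, cap - first_pos)
        ae_times = schedule_adverse_events(plan, horizon, ctx.ae_uniform_stream(pid))
        disc = truncate_at_first_detected_ae(plan, disc, ae_times)

    delayed = onset
    if onset is not None:
        stop = None if math.isinf(disc) else first_pos + disc
        delayed = apply_progression_slowdown(onset, first_pos, stop, plan.effectiveness)

    # therapy ends at the earliest of discontinuation, (delayed) onset,
    # death, or the age cap
    stop_age = min(
        first_pos + disc,
        delayed if delayed is not None else math.inf,
        death,
        cap,
    )
    duration = max(0.0, stop_age - first_pos)

    n_ae = 0
    if cfg.count_adverse_events and duration > 0:
        if not plan.discontinue_on_ae:
            ae_times = schedule_adverse_events(plan, duration, ctx.ae_uniform_stream(pid))
        n_ae = sum(1 for t in ae_times if t <= duration)

    screen_traj = PatientTrajectory(
        id=pid,
        sex=sex,  # type: ignore[arg-type]
        arm="screening",
        scheduled_onset_age=onset,
        death_age=death,
        first_positive_age=first_pos,
        treatment_start_age=first_pos,
        treatment_stop_age=stop_age,
        realized_onset_age=case(delayed),
        ad_free_years=free_years(delayed),
        treatment_years=_years(first_pos, first_pos + duration, cfg)
        if cfg.discounting_enabled
        else duration,
        n_adverse_events=n_ae,
    )
    return base, screen_traj


def simulate_patient(
    config: SimulationConfig, patient_id: int = 0
) -> tuple[PatientTrajectory, PatientTrajectory]:
    """Simulate one patient in both arms under common random numbers.

    Draws are identical to the ones patient ``patient_id`` receives inside
    ``simulate_cohort`` with the same seed, whatever the cohort size.
    """
    ctx = _Context(config, patient_id + 1)
    return _simulate_one(ctx, patient_id)


@dataclass(frozen=True)
class ArmTotals:
    """Raw per-arm totals over the simulated cohort (not per-1000)."""

    n: int
    ad_free_years: float
    ad_cases: int
    treatment_years: float
    n_recommended: int
    adverse_events: int


@dataclass(frozen=True)
class CohortResult:
    config: SimulationConfig
    no_screening: ArmTotals
    screening: ArmTotals
    incremental_ad_free_years: float
    incremental_ad_free_years_avoiders: float
    trace: pd.DataFrame | None = None
    screen_trace: pd.DataFrame | None = None

    @property
    def cases_avoided(self) -> int:
        return self.no_screening.ad_cases - self.screening.ad_cases

    @property
    def avoider_share(self) -> float:
        """Share of incremental AD-free years accruing to patients whose
        onset was pushed past death or the age cap (complete avoiders)."""
        if self.incremental_ad_free_years <= 0:
            return math.nan
        return self.incremental_ad_free_years_avoiders / self.incremental_ad_free_years


def simulate_cohort(config: SimulationConfig, trace: bool = False) -> CohortResult:
    """Run the paired cohort; deterministic given (config, seed)."""
    n = config.cohort_size
    ctx = _Context(config, n)
    adfy = np.zeros(2)
    ty = np.zeros(2)
    cases = np.zeros(2, dtype=int)
    recommended = np.zeros(2, dtype=int)
    aes = np.zeros(2, dtype=int)
    incr_total = 0.0
    incr_avoiders = 0.0
    rows: list[PatientTrajectory] = []
    screen_log: list[tuple] | None = [] if trace else None

    for pid in range(n):
        ns, sc = _simulate_one(ctx, pid, screen_log)
        for i, tr in enumerate((ns, sc)):
            adfy[i] += tr.ad_free_years
            ty[i] += tr.treatment_years
            cases[i] += tr.is_case
            recommended[i] += tr.first_positive_age is not None
            aes[i] += tr.n_adverse_events
        gain = sc.ad_free_years - ns.ad_free_years
        incr_total += gain
        if ns.is_case and not sc.is_case:
            incr_avoiders += gain
        if trace:
            rows.extend((ns, sc))

    trace_df = pd.DataFrame([vars(t) for t in rows]) if trace else None
    screen_df = (
        pd.DataFrame(screen_log, columns=["id", "screen_age", "truth", "result"])
        if trace
        else None
    )
    return CohortResult(
        config=config,
        no_screening=ArmTotals(n, float(adfy[0]), int(cases[0]), float(ty[0]),
                               int(recommended[0]), int(aes[0])),
        screening=ArmTotals(n, float(adfy[1]), int(cases[1]), float(ty[1]),
                            int(recommended[1]), int(aes[1])),
        incremental_ad_free_years=float(incr_total),
        incremental_ad_free_years_avoiders=float(incr_avoiders),
        trace=trace_df,
        screen_trace=screen_df,
    )


# ---------------------------------------------------------------------------
# Analytic cross-checks (no simulation): used for fixture calibration and as
# independent oracles against the Monte Carlo engine.


def analytic_ad_free_years(config: SimulationConfig) -> float:
    """Expected undiscounted AD-free years per person in the no-screening arm:
    E[min(T_onset, T_death, cap) - entry], mixed over sex."""
    ctx_table = generate_fixture(config.mortality)
    entry = config.entry_age
    total = 0.0
    for sex, w in (("male", config.pct_male), ("female", 1.0 - config.pct_male)):
        hz_on = build_hazard(
            config.incidence, sex, entry, "piecewise_exponential", config.anchored_incidence
        )
        hz_d = death_hazard(ctx_table, sex, entry)
        total += w * expected_min_event_time([hz_on, hz_d], config.age_cap - entry)
    return total


def analytic_case_probability(config: SimulationConfig) -> float:
    """P(scheduled onset precedes death and the age cap), mixed over sex."""
    table = generate_fixture(config.mortality)
    entry = config.entry_age
    total = 0.0
    for sex, w in (("male", config.pct_male), ("female", 1.0 - config.pct_male)):
        hz_on = build_hazard(
            config.incidence, sex, entry, "piecewise_exponential", config.anchored_incidence
        )
        hz_d = death_hazard(table, sex, entry)
        total += w * competing_event_probability(hz_on, hz_d, config.age_cap - entry)
    return total
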