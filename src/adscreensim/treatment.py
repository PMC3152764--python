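"""Preventive therapy: progression-clock slowdown, persistence, adverse events.

Therapy with effectiveness ``e`` slows the disease clock to rate ``1 - e``
while the patient is on it; off therapy the clock runs at rate 1.  A patient
with residual time ``r`` to scheduled onset who stays on therapy until onset
is therefore delayed by ``r * e / (1 - e)`` — for e = 0.5, doubling the
remaining pre-onset time (the geometric limit t/2 + t/4 + ... -> t).

Persistence is modeled as two first-year discontinuation blocks (first and
second six months) followed by a long-term rule; adverse events arrive from a
piecewise-constant annual-rate schedule and, in the base case, are counted
without altering the course of therapy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "PersistencePattern",
    "TreatmentPlan",
    "PERSISTENCE_PRESETS",
    "sample_discontinuation_time",
    "apply_progression_slowdown",
    "schedule_adverse_events",
    "truncate_at_first_detected_ae",
    "ae_detection_time",
]


@dataclass(frozen=True)
class PersistencePattern:
    """Block discontinuation probabilities for year 1, then a long-term rule.

    ``after_year_one`` is either ``"persist_until_onset"`` (no further
    discontinuation; therapy runs to onset or death) or an annual
    discontinuation probability applied as a constant hazard.
    """

    name: str
    p_disc_first_6mo: float
    p_disc_second_6mo: float
    after_year_one: float | Literal["persist_until_onset"] = "persist_until_onset"

    def __post_init__(self) -> None:
        for p in (self.p_disc_first_6mo, self.p_disc_second_6mo):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"block probability {p} outside [0, 1]")
        if self.after_year_one != "persist_until_onset":
            if not 0.0 <= float(self.after_year_one) <= 1.0:
                raise ValueError("annual discontinuation probability outside [0, 1]")


#: Named persistence patterns; the base case mirrors tamoxifen for prevention
#: of breast-cancer recurrence (~22% stop in year 1, the rest persist to onset).
PERSISTENCE_PRESETS: dict[str, PersistencePattern] = {
    "base_case_tamoxifen": PersistencePattern("base_case_tamoxifen", 0.17, 0.051),
    "tamoxifen": PersistencePattern("tamoxifen", 0.17, 0.051),
    "ad_ci_model_1": PersistencePattern("ad_ci_model_1", 0.0, 0.68),
    "ad_ci_model_2": PersistencePattern("ad_ci_model_2", 0.0, 0.47),
    "ace_inhibitors": PersistencePattern("ace_inhibitors", 0.25, 0.04),
    "unending": PersistencePattern("unending", 0.0, 0.0),
}


@dataclass(frozen=True)
class TreatmentPlan:
    """Therapy effectiveness, persistence, and the adverse-event schedule.

    ``effectiveness`` is the clock-slowdown fraction e in [0, 1).  AE periods
    are ``(years_lo, years_hi, annual_probability)`` measured from therapy
    initiation and must be contiguous from 0.
    """

    effectiveness: float = 0.5
    persistence: PersistencePattern = PERSISTENCE_PRESETS["base_case_tamoxifen"]
    ae_rates: tuple[tuple[float, float, float], ...] = (
        (0.0, 1.0, 0.10),
        (1.0, 5.0, 0.02),
        (5.0, 10.0, 0.02),
        (10.0, 15.0, 0.02),
        (15.0, 20.0, 0.02),
    )
    discontinue_on_ae: bool = False
    ae_monitoring_interval_first_year: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.effectiveness < 1.0:
            raise ValueError("effectiveness must be in [0, 1)")
        prev = 0.0
        for lo, hi, rate in self.ae_rates:
            if lo != prev or hi <= lo:
                raise ValueError("AE periods must be contiguous from 0")
            if not 0.0 <= rate <= 1.0:
                raise ValueError("AE annual probability outside [0, 1]")
            prev = hi
        if self.ae_monitoring_interval_first_year <= 0:
            raise ValueError("monitoring interval must be positive")


def sample_discontinuation_time(
    pattern: PersistencePattern, u1: float, u2: float, u3: float
) -> float:
    """Duration on therapy (years) before discontinuation; ``inf`` if unending.

    With probability ``p_disc_first_6mo`` the stop time is uniform in
    (0, 0.5]; failing that, with ``p_disc_second_6mo`` uniform in (0.5, 1];
    otherwise the long-term rule applies from the end of year 1.  Times within
    each block are uniform — the published pattern pins only block totals.
    """
    for u in (u1, u2, u3):
        if not 0.0 < u < 1.0:
            raise ValueError("uniform draws must lie strictly inside (0, 1)")
    if u1 < pattern.p_disc_first_6mo:
        return 0.5 * u3 if u3 > 0 else 0.5
    if u2 < pattern.p_disc_second_6mo:
        return 0.5 + 0.5 * u3
    if pattern.after_year_one == "persist_until_onset":
        return math.inf
    annual = float(pattern.after_year_one)
    if annual <= 0.0:
        return math.inf
    lam = -math.log1p(-annual) if annual < 1.0 else math.inf
    if math.isinf(lam):
        return 1.0
    return 1.0 + (-math.log(u3)) / lam


def apply_progression_slowdown(
    onset_age: float,
    treat_start_age: float,
    treat_stop_age: float | None,
    effectiveness: float,
) -> float:
    """Delayed onset age under the clock-slowdown mechanism.

    The disease clock advances at rate ``1 - e`` on therapy and 1 off it.
    With residual ``r = onset_age - treat_start_age`` and on-therapy duration
    ``d``: onset occurs on therapy (at ``start + r / (1 - e)``) when
    ``d * (1 - e) >= r``, else the clock finishes off therapy at
    ``start + d + (r - d * (1 - e))``.  ``treat_stop_age=None`` means therapy
    continues until onset.
    """
    if not 0.0 <= effectiveness < 1.0:
        raise ValueError("effectiveness must be in [0, 1)")
    if treat_start_age >= onset_age:
        raise ValueError("treatment must start before scheduled onset")
    r = onset_age - treat_start_age
    slow = 1.0 - effectiveness
    d = math.inf if treat_stop_age is None else treat_stop_age - treat_start_age
    if d < 0:
        raise ValueError("treatment stop precedes start")
    if d * slow >= r:
        return treat_start_age + r / slow
    return treat_start_age + d + (r - d * slow)


def _ae_cumulative_hazard(plan: TreatmentPlan, horizon: float) -> tuple[np.ndarray, np.ndarray]:
    edges = [0.0]
    rates = []
    for lo, hi, p in plan.ae_rates:
        if lo >= horizon:
            break
        edges.append(min(hi, horizon))
        rates.append(-math.log1p(-min(p, 1.0 - 1e-12)))
    edges_arr = np.asarray(edges)
    ch = np.concatenate(([0.0], np.cumsum(np.asarray(rates) * np.diff(edges_arr))))
    return edges_arr, ch


def schedule_adverse_events(
    plan: TreatmentPlan, therapy_duration: float, u_stream: Iterable[float]
) -> list[float]:
    """Adverse-event times (years from therapy start) over the on-therapy
    interval, sampled from the piecewise-constant annual rates as a
    non-homogeneous Poisson process by sequential cumulative-hazard inversion.

    Consumes one uniform per event generated (plus one terminating draw).
    """
    if therapy_duration <= 0:
        return []
    horizon = min(therapy_duration, plan.ae_rates[-1][1]) if plan.ae_rates else 0.0
    if horizon <= 0:
        return []
    edges, ch = _ae_cumulative_hazard(plan, horizon)
    if ch[-1] <= 0:
        return []
    times: list[float] = []
    h = 0.0
    us = iter(u_stream)
    while True:
        try:
            u = next(us)
        except StopIteration:
            raise RuntimeError("uniform stream exhausted while scheduling AEs") from None
        h += -math.log(u)
        if h > ch[-1]:
            return times
        times.append(float(np.interp(h, ch, edges)))


def ae_detection_time(plan: TreatmentPlan, ae_time: float) -> float:
    """First monitoring visit at or after an AE (years from therapy start).

    Monitoring runs every ``ae_monitoring_interval_first_year`` during year 1
    and annually thereafter.
    """
    if ae_time <= 1.0:
        step = plan.ae_monitoring_interval_first_year
        return math.ceil(ae_time / step - 1e-12) * step
    return math.ceil(ae_time - 1e-12)


def truncate_at_first_detected_ae(
    plan: TreatmentPlan, therapy_duration: float, ae_times: list[float]
) -> float:
    """Therapy duration after the discontinue-on-AE rule.

    With the flag off (base case) the duration is unchanged; with it on,
    therapy stops at the first monitoring visit following the first AE, if
    that visit falls before the scheduled end of therapy.
    """
    if not plan.discontinue_on_ae or not ae_times:
        return therapy_duration
    detect = ae_detection_time(plan, min(ae_times))
    return min(therapy_duration, detect)
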