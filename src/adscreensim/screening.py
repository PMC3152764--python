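"""Biomarker screen with a finite duration of sensitivity, and the rescreen policy.

The screen detects pre-symptomatic disease at its stated sensitivity only
when scheduled onset lies within ``duration_of_sensitivity`` years of the
screen; a patient further from onset is indistinguishable from one who will
never convert, so the positive rate falls back to 1 − specificity.  The
policy screens at the first-screen age and every rescreen interval until the
first positive, clinical onset, death, or the stop age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Literal

__all__ = ["ScreeningTest", "ScreenOutcome", "screen_once", "run_screening_policy", "screen_ages"]


@dataclass(frozen=True)
class ScreeningTest:
    """Operating characteristics and schedule of the screen.

    ``rescreen_interval`` of ``None`` means screen once.  ``stop_age`` of
    ``None`` defaults to the age cap (100) minus one interval for repeated
    screening, and to the first-screen age for a single screen.
    """

    sensitivity: float = 0.87
    specificity: float = 0.78
    duration_of_sensitivity: float = 10.0
    first_screen_age: float = 70.0
    rescreen_interval: float | None = None
    stop_age: float | None = None
    age_cap: float = 100.0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.duration_of_sensitivity <= 0:
            raise ValueError("duration_of_sensitivity must be positive")
        if self.rescreen_interval is not None and self.rescreen_interval <= 0:
            raise ValueError("rescreen_interval must be positive or None")
        if self.stop_age is not None and self.stop_age < self.first_screen_age:
            raise ValueError("stop_age must be at or after first_screen_age")

    @property
    def effective_stop_age(self) -> float:
        if self.stop_age is not None:
            return self.stop_age
        if self.rescreen_interval is None:
            return self.first_screen_age
        return self.age_cap - self.rescreen_interval


def screen_ages(test: ScreeningTest) -> Iterator[float]:
    """Ages at which screens are scheduled (ignoring patient events)."""
    age = test.first_screen_age
    stop = test.effective_stop_age
    while age <= stop + 1e-12:
        yield age
        if test.rescreen_interval is None:
            return
        age += test.rescreen_interval


@dataclass(frozen=True)
class ScreenOutcome:
    screen_age: float
    result: Literal["positive", "negative"]
    truth: Literal["onset_within_window", "onset_beyond_window_or_never"]


def screen_once(
    scheduled_onset_age: float | None,
    screen_age: float,
    test: ScreeningTest,
    u: float,
) -> ScreenOutcome:
    """One screen: positive at ``sensitivity`` when onset is within the
    detection window (closed at the boundary), else at ``1 - specificity``.

    Requires the screen to precede any scheduled onset — nobody has clinical
    disease at the time of screening.
    """
    if scheduled_onset_age is not None and screen_age >= scheduled_onset_age:
        raise ValueError("screen scheduled at or after clinical onset")
    if not 0.0 < u < 1.0:
        raise ValueError("uniform draw must lie strictly inside (0, 1)")
    within = (
        scheduled_onset_age is not None
        and scheduled_onset_age - screen_age <= test.duration_of_sensitivity
    )
    p_pos = test.sensitivity if within else 1.0 - test.specificity
    return ScreenOutcome(
        screen_age=screen_age,
        result="positive" if u < p_pos else "negative",
        truth="onset_within_window" if within else "onset_beyond_window_or_never",
    )


def run_screening_policy(
    scheduled_onset_age: float | None,
    death_age: float,
    test: ScreeningTest,
    u_stream: Iterable[float],
    record: list[ScreenOutcome] | None = None,
) -> float | None:
    """Age of the first positive screen, or ``None`` if no screen is positive.

    Screens stop at the earliest of: first positive (treatment starts, no
    further screens), death, scheduled onset (clinical diagnosis supersedes
    screening), or the stop age.  Consumes exactly one uniform per screen
    performed; every screen performed is appended to ``record`` when given.
    """
    us = iter(u_stream)
    for age in screen_ages(test):
        if age >= death_age:
            return None
        if scheduled_onset_age is not None and age >= scheduled_onset_age:
            return None
        try:
            u = next(us)
        except StopIteration:
            raise RuntimeError("uniform stream exhausted before screening ended") from None
        outcome = screen_once(scheduled_onset_age, age, test, u)
        if record is not None:
            record.append(outcome)
        if outcome.result == "positive":
            return age
    return None
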