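"""Age/sex-stratified incidence hazards and inverse-transform event sampling.

Annual onset probabilities are published per age stratum; event times are
drawn in continuous time by converting each stratum's annual probability to a
constant hazard rate, integrating to a cumulative-hazard curve, and inverting
a single uniform draw.  Two within-stratum approximations of the cumulative
curve are supported: ``piecewise_exponential`` (exact for piecewise-constant
hazards) and ``piecewise_linear`` (linear interpolation of the cumulative
probability between stratum boundaries).  The two agree exactly at every
boundary knot and differ only inside strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

Sex = Literal["male", "female"]
Method = Literal["piecewise_exponential", "piecewise_linear"]

__all__ = [
    "IncidenceSchedule",
    "HazardFunction",
    "DEFAULT_INCIDENCE",
    "annual_prob_to_rate",
    "build_hazard",
    "sample_event_time",
    "cumulative_probability",
    "expected_min_event_time",
    "competing_event_probability",
    "read_incidence_csv",
    "write_incidence_csv",
]


def annual_prob_to_rate(p: float) -> float:
    """Constant hazard rate (events/year) matching an annual event probability.

    Solves ``1 - exp(-lam * 1yr) = p`` for ``lam``, i.e. ``lam = -ln(1 - p)``.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"annual probability must be in [0, 1), got {p}")
    return float(-np.log1p(-p))


@dataclass(frozen=True)
class IncidenceSchedule:
    """Annual onset probabilities per age stratum, by sex.

    Each stratum is ``(age_lo, age_hi, prob_male, prob_female)`` with the
    upper bound exclusive; strata must be contiguous, sorted, and the last
    stratum runs to ``terminal_age`` (age cap, default 100).  ``anchor_ages``
    optionally give the representative age inside each stratum used by the
    anchored (rate-interpolating) hazard mode.
    """

    strata: tuple[tuple[float, float, float, float], ...]
    terminal_age: float = 100.0
    anchor_ages: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("schedule needs at least one stratum")
        prev_hi = None
        for lo, hi, pm, pf in self.strata:
            if hi <= lo:
                raise ValueError(f"empty stratum [{lo}, {hi})")
            if prev_hi is not None and lo != prev_hi:
                raise ValueError("strata must be contiguous and sorted")
            for p in (pm, pf):
                if not 0.0 <= p < 1.0:
                    raise ValueError(f"annual probability {p} outside [0, 1)")
            prev_hi = hi
        if self.strata[-1][1] != self.terminal_age:
            raise ValueError("last stratum must end at terminal_age")
        if self.anchor_ages is not None and len(self.anchor_ages) != len(self.strata):
            raise ValueError("one anchor age per stratum required")

    def annual_prob(self, age: float, sex: Sex) -> float:
        """Annual onset probability in force at ``age`` (0 outside strata)."""
        col = _sex_col(sex)
        for row in self.strata:
            if row[0] <= age < row[1]:
                return row[col]
        return 0.0


def _sex_col(sex: str) -> int:
    if sex == "male":
        return 2
    if sex == "female":
        return 3
    raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


#: Base-case age/sex annual probabilities of developing AD (Framingham-derived
#: incidence, zero below 65, constant for ages 85-100).
DEFAULT_INCIDENCE = IncidenceSchedule(
    strata=(
        (50.0, 55.0, 0.0, 0.0),
        (55.0, 60.0, 0.0, 0.0),
        (60.0, 65.0, 0.0, 0.0),
        (65.0, 70.0, 0.0007, 0.0002),
        (70.0, 75.0, 0.0014, 0.0004),
        (75.0, 80.0, 0.0025, 0.003),
        (80.0, 85.0, 0.0065, 0.0074),
        (85.0, 100.0, 0.016, 0.03),
    ),
    terminal_age=100.0,
    # the terminal stratum is constant over 85-100, so its anchor sits at 85
    anchor_ages=(52.0, 57.0, 62.0, 67.0, 72.0, 77.0, 82.0, 85.0),
)


@dataclass(frozen=True)
class HazardFunction:
    """Cumulative-hazard curve on age knots, with an interpolation method.

    ``knots`` are ages (years); ``cum_hazard`` is the dimensionless cumulative
    hazard at each knot, starting at 0.  Between knots the hazard rate is
    constant (cumulative hazard linear).  ``method`` selects how the
    *cumulative probability* curve is read between knots when sampling:
    exactly (``piecewise_exponential``) or by linear interpolation of the
    knot probabilities (``piecewise_linear``).
    """

    knots: np.ndarray
    cum_hazard: np.ndarray
    method: Method = "piecewise_exponential"

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        ch = np.asarray(self.cum_hazard, dtype=float)
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "cum_hazard", ch)
        if knots.ndim != 1 or knots.shape != ch.shape or len(knots) < 2:
            raise ValueError("knots and cum_hazard must be matching 1-d arrays")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if ch[0] != 0.0 or np.any(np.diff(ch) < 0):
            raise ValueError("cumulative hazard must start at 0 and be non-decreasing")
        if self.method not in ("piecewise_exponential", "piecewise_linear"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def origin(self) -> float:
        return float(self.knots[0])

    @property
    def horizon(self) -> float:
        """Time span covered by the curve (years from origin)."""
        return float(self.knots[-1] - self.knots[0])

    def cum_prob_at_knots(self) -> np.ndarray:
        return -np.expm1(-self.cum_hazard)


def build_hazard(
    schedule: IncidenceSchedule,
    sex: Sex,
    from_age: float,
    method: Method = "piecewise_exponential",
    anchored: bool = False,
) -> HazardFunction:
    """Cumulative onset hazard for one sex, starting at ``from_age``.

    The curve starts at 0 at ``from_age``, integrates the per-stratum constant
    rates up to ``terminal_age``, and is flat beyond it (events past the age
    cap never occur; the sampler returns ``None`` for them).  With
    ``anchored=True`` the hazard rate is interpolated linearly between the
    strata's anchor ages (evaluated per 1-year sub-interval at the midpoint)
    instead of held constant per stratum; knot values then differ from the
    constant-rate reading except where the rate is locally flat.
    """
    col = _sex_col(sex)
    if from_age >= schedule.terminal_age:
        raise ValueError("from_age must be below terminal_age")

    if anchored:
        if schedule.anchor_ages is None:
            raise ValueError("anchored mode requires anchor_ages on the schedule")
        edges = np.arange(from_age, schedule.terminal_age, 1.0)
        edges = np.append(edges, schedule.terminal_age)
        anchors = np.asarray(schedule.anchor_ages)
        probs = np.array([row[col] for row in schedule.strata])
        mids = 0.5 * (edges[:-1] + edges[1:])
        p_mid = np.interp(mids, anchors, probs)
        rates = -np.log1p(-p_mid)
    else:
        bounds = [from_age]
        for lo, hi, *_ in schedule.strata:
            if hi > from_age:
                bounds.append(hi)
        edges = np.asarray(bounds, dtype=float)
        rates = np.array(
            [annual_prob_to_rate(schedule.annual_prob(lo, sex)) for lo in edges[:-1]]
        )

    ch = np.concatenate(([0.0], np.cumsum(rates * np.diff(edges))))
    return HazardFunction(knots=edges, cum_hazard=ch, method=method)


def cumulative_probability(hazard: HazardFunction, t: float | np.ndarray) -> np.ndarray | float:
    """P(event time <= t), with t in years from the curve origin.

    Honors the hazard's interpolation method between knots; flat (probability
    frozen) beyond the last knot.
    """
    tt = np.clip(np.asarray(t, dtype=float), 0.0, hazard.horizon)
    rel = hazard.knots - hazard.origin
    if hazard.method == "piecewise_exponential":
        h = np.interp(tt, rel, hazard.cum_hazard)
        out = -np.expm1(-h)
    else:
        out = np.interp(tt, rel, hazard.cum_prob_at_knots())
    return out if np.ndim(t) else float(out)


def _invert_nondecreasing(xs: np.ndarray, ys: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Left-continuous inverse of a non-decreasing curve y(x) at given targets.

    Flat stretches map to their left endpoint (an interval of zero hazard can
    not contain the event).  Targets above max(y) yield NaN.
    """
    # keep the first x achieving each y so ties resolve leftward
    keep = np.concatenate(([True], np.diff(ys) > 0))
    xs_u, ys_u = xs[keep], ys[keep]
    out = np.interp(targets, ys_u, xs_u)
    out = np.where(targets > ys[-1], np.nan, out)
    return out


def invert_survival(hazard: HazardFunction, u: np.ndarray) -> np.ndarray:
    """Vectorized inverse-transform: event times (years from origin) for
    uniforms ``u``; NaN where the event falls beyond the horizon."""
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("uniform draws must lie strictly inside (0, 1)")
    rel = hazard.knots - hazard.origin
    if hazard.method == "piecewise_exponential":
        target = -np.log(u)
        return _invert_nondecreasing(rel, hazard.cum_hazard, target)
    target = 1.0 - u
    return _invert_nondecreasing(rel, hazard.cum_prob_at_knots(), target)


def sample_event_time(hazard: HazardFunction, u: float) -> float | None:
    """Inverse-transform a single event time from one uniform draw.

    Returns ``t`` (years from the curve origin) with ``S(t) = u`` under the
    hazard's method, or ``None`` when the cumulative probability over the
    horizon is below ``1 - u`` — the event is scheduled beyond the age cap and
    never occurs.
    """
    t = float(invert_survival(hazard, np.asarray([u]))[0])
    return None if np.isnan(t) else t


# ---------------------------------------------------------------------------
# Analytic helpers over piecewise-constant-hazard curves (used for fixture
# calibration and as independent oracles in tests).


def _merged_grid(hazards: Sequence[HazardFunction]) -> tuple[np.ndarray, np.ndarray]:
    """Merged relative-time knot grid and per-segment total rates."""
    rel_knots = [hz.knots - hz.origin for hz in hazards]
    grid = np.unique(np.concatenate(rel_knots))
    grid = grid[grid <= min(k[-1] for k in rel_knots)]
    total = np.zeros(len(grid) - 1)
    for hz, rel in zip(hazards, rel_knots):
        h = np.interp(grid, rel, hz.cum_hazard)
        total += np.diff(h) / np.diff(grid)
    return grid, total


def expected_min_event_time(hazards: Sequence[HazardFunction], horizon: float) -> float:
    """E[min(T_1, ..., T_k, horizon)] for independent piecewise-constant-rate
    event times sharing an origin; times in years from the origin."""
    grid, rates = _merged_grid(hazards)
    grid = np.clip(grid, 0.0, horizon)
    widths = np.diff(grid)
    surv = 1.0
    total = 0.0
    t_done = 0.0
    for w, lam in zip(widths, rates):
        if w <= 0:
            continue
        if lam > 0:
            total += surv * -np.expm1(-lam * w) / lam
        else:
            total += surv * w
        surv *= np.exp(-lam * w)
        t_done += w
    total += surv * max(0.0, horizon - t_done)
    return float(total)


def competing_event_probability(
    event: HazardFunction, competitor: HazardFunction, horizon: float
) -> float:
    """P(T_event < min(T_competitor, horizon)) under independence.

    Closed form per merged segment: lam_e/lam_tot * (survival mass absorbed in
    the segment).
    """
    grid, _ = _merged_grid([event, competitor])
    grid = grid[grid <= horizon]
    if grid[-1] < horizon:
        grid = np.append(grid, horizon)
    rel_e = event.knots - event.origin
    rel_c = competitor.knots - competitor.origin
    h_e = np.interp(grid, rel_e, event.cum_hazard)
    h_c = np.interp(grid, rel_c, competitor.cum_hazard)
    lam_e = np.diff(h_e) / np.diff(grid)
    lam_tot = lam_e + np.diff(h_c) / np.diff(grid)
    surv = np.exp(-(h_e + h_c))[:-1]
    absorbed = surv * -np.expm1(-lam_tot * np.diff(grid))
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(lam_tot > 0, lam_e / lam_tot, 0.0)
    return float(np.sum(share * absorbed))


# ---------------------------------------------------------------------------
# Delimited-text round trip.


def write_incidence_csv(schedule: IncidenceSchedule, path_or_buf) -> None:
    df = pd.DataFrame(
        list(schedule.strata), columns=["age_lo", "age_hi", "prob_male", "prob_female"]
    )
    df.to_csv(path_or_buf, index=False)


def read_incidence_csv(path_or_buf, terminal_age: float = 100.0) -> IncidenceSchedule:
    df = pd.read_csv(path_or_buf)
    strata = tuple(
        (float(r.age_lo), float(r.age_hi), float(r.prob_male), float(r.prob_female))
        for r in df.itertuples()
    )
    return IncidenceSchedule(strata=strata, terminal_age=terminal_age)
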