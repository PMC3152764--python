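"""Incidence hazards: probability↔rate conversion, curve building, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adscreensim.hazards import (
    DEFAULT_INCIDENCE,
    HazardFunction,
    IncidenceSchedule,
    annual_prob_to_rate,
    build_hazard,
    cumulative_probability,
    invert_survival,
    sample_event_time,
)

ALL_ZERO = IncidenceSchedule(strata=((50.0, 100.0, 0.0, 0.0),))


@pytest.mark.parametrize(
    "p, expected",
    [
        (0.0, 0.0),
        (0.03, -math.log(0.97)),
        (0.0074, -math.log(0.9926)),  # female 80-84 stratum value
    ],
)
def test_annual_prob_to_rate_closed_form(p, expected):
    lam = annual_prob_to_rate(p)
    assert lam == pytest.approx(expected, rel=1e-12)
    # the rate reproduces the annual probability exactly
    assert 1.0 - math.exp(-lam) == pytest.approx(p, abs=1e-12)


@pytest.mark.parametrize("p", [-0.01, 1.0, 1.5])
def test_annual_prob_to_rate_rejects_out_of_domain(p):
    with pytest.raises(ValueError):
        annual_prob_to_rate(p)


def test_zero_schedule_has_zero_hazard_and_never_fires():
    hz = build_hazard(ALL_ZERO, "female", 70.0)
    assert np.all(hz.cum_hazard == 0.0)
    for u in (0.001, 0.5, 0.999):
        assert sample_event_time(hz, u) is None


def _boundary_probability_oracle(sex: str, from_age: float) -> dict[float, float]:
    """Independent oracle: cumulative onset probability at each stratum
    boundary as 1 - prod over whole years of (1 - annual prob)."""
    out = {}
    surv = 1.0
    age = from_age
    for lo, hi, pm, pf in DEFAULT_INCIDENCE.strata:
        if hi <= from_age:
            continue
        p = pm if sex == "male" else pf
        years = int(hi - max(lo, from_age))
        surv *= (1.0 - p) ** years
        out[hi] = 1.0 - surv
    return out


@pytest.mark.parametrize("sex", ["male", "female"])
def test_cumulative_probability_matches_annual_product_at_boundaries(sex):
    hz = build_hazard(DEFAULT_INCIDENCE, sex, 70.0, "piecewise_exponential")
    for age, expected in _boundary_probability_oracle(sex, 70.0).items():
        got = cumulative_probability(hz, age - 70.0)
        assert got == pytest.approx(expected, rel=1e-10)


def test_hazard_steeper_in_80s_than_70s_stratum():
    hz = build_hazard(DEFAULT_INCIDENCE, "female", 70.0)
    per_year_75 = cumulative_probability(hz, 8.0) - cumulative_probability(hz, 7.0)
    per_year_82 = cumulative_probability(hz, 12.0) - cumulative_probability(hz, 11.0)
    assert per_year_82 > per_year_75


@pytest.mark.parametrize("anchored", [False, True])
def test_linear_and_exponential_agree_exactly_at_knots(anchored):
    hz_e = build_hazard(DEFAULT_INCIDENCE, "female", 70.0, "piecewise_exponential", anchored)
    hz_l = build_hazard(DEFAULT_INCIDENCE, "female", 70.0, "piecewise_linear", anchored)
    np.testing.assert_array_equal(hz_e.knots, hz_l.knots)
    for t in hz_e.knots - hz_e.origin:
        assert cumulative_probability(hz_e, t) == pytest.approx(
            cumulative_probability(hz_l, t), abs=1e-14
        )


def test_exponential_inversion_identity_single_rate():
    # one stratum, constant annual probability: S(t) = exp(-lam t)
    sched = IncidenceSchedule(strata=((50.0, 100.0, 0.05, 0.05),))
    hz = build_hazard(sched, "male", 50.0)
    lam = annual_prob_to_rate(0.05)
    t0 = 3.7
    assert sample_event_time(hz, math.exp(-lam * t0)) == pytest.approx(t0, rel=1e-10)


def _grid_inversion_oracle(hz: HazardFunction, u: np.ndarray, dt: float = 0.01) -> np.ndarray:
    """Brute-force sampler: tabulate the CDF on a fine grid and pick the first
    grid time where it reaches 1-u."""
    grid = np.arange(0.0, hz.horizon + dt, dt)
    cdf = np.asarray(cumulative_probability(hz, grid))
    idx = np.searchsorted(cdf, 1.0 - u, side="left")
    out = np.where(idx < len(grid), grid[np.minimum(idx, len(grid) - 1)], np.nan)
    out[1.0 - u > cdf[-1]] = np.nan
    return out


@pytest.mark.parametrize("method", ["piecewise_exponential", "piecewise_linear"])
def test_sampled_times_match_brute_force_grid_inversion(method, rng):
    hz = build_hazard(DEFAULT_INCIDENCE, "female", 70.0, method)
    u = np.clip(rng.random(100_000), 1e-12, 1 - 1e-12)
    fast = invert_survival(hz, u)
    slow = _grid_inversion_oracle(hz, u)
    assert np.array_equal(np.isnan(fast), np.isnan(slow))
    ok = ~np.isnan(fast)
    # grid resolution bounds the discrepancy
    assert np.max(np.abs(fast[ok] - slow[ok])) <= 0.011

    # Kolmogorov-Smirnov distance between the empirical CDF of the samples
    # and the analytic cumulative curve
    times = np.sort(fast[ok])
    analytic = np.asarray(cumulative_probability(hz, times))
    emp_hi = np.arange(1, len(times) + 1) / len(u)
    emp_lo = np.arange(0, len(times)) / len(u)
    ks = max(np.max(np.abs(emp_hi - analytic)), np.max(np.abs(emp_lo - analytic)))
    assert ks < 1.63 / math.sqrt(len(u)) + 1e-3  # ~alpha=0.01 band


@given(scale=st.floats(1.0, 20.0), age=st.floats(71.0, 99.0))
def test_scaling_incidence_up_raises_event_probability(scale, age):
    strata = tuple(
        (lo, hi, min(pm * scale, 0.97), min(pf * scale, 0.97))
        for lo, hi, pm, pf in DEFAULT_INCIDENCE.strata
    )
    scaled = IncidenceSchedule(strata=strata, terminal_age=100.0)
    hz = build_hazard(DEFAULT_INCIDENCE, "female", 70.0)
    hz_up = build_hazard(scaled, "female", 70.0)
    assert cumulative_probability(hz_up, age - 70.0) >= cumulative_probability(hz, age - 70.0)


def test_sampling_is_pure():
    hz = build_hazard(DEFAULT_INCIDENCE, "male", 70.0)
    assert sample_event_time(hz, 0.8) == sample_event_time(hz, 0.8)


@pytest.mark.parametrize("u", [0.0, 1.0, -0.2, 1.3])
def test_sampler_rejects_degenerate_uniforms(u):
    hz = build_hazard(DEFAULT_INCIDENCE, "male", 70.0)
    with pytest.raises(ValueError):
        sample_event_time(hz, u)


def test_schedule_validation():
    with pytest.raises(ValueError):
        IncidenceSchedule(strata=((50.0, 60.0, 0.0, 0.0), (65.0, 100.0, 0.01, 0.01)))
    with pytest.raises(ValueError):
        IncidenceSchedule(strata=((50.0, 100.0, 1.0, 0.5),))
    with pytest.raises(ValueError):
        build_hazard(DEFAULT_INCIDENCE, "other", 70.0)
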