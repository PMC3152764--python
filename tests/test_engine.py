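"""Paired-arm engine: common random numbers, tie-breaks, aggregation."""

import dataclasses
import math

import numpy as np
import pytest

from adscreensim.engine import (
    SimulationConfig,
    analytic_ad_free_years,
    analytic_case_probability,
    simulate_cohort,
    simulate_patient,
)
from adscreensim.hazards import IncidenceSchedule
from adscreensim.screening import ScreeningTest
from adscreensim.treatment import PERSISTENCE_PRESETS, TreatmentPlan

ZERO_INCIDENCE = IncidenceSchedule(strata=((50.0, 100.0, 0.0, 0.0),), anchor_ages=(75.0,))


def _cfg(**kw) -> SimulationConfig:
    kw.setdefault("cohort_size", 2000)
    kw.setdefault("seed", 11)
    return SimulationConfig(**kw)


def test_no_disease_and_no_positive_yields_identical_arms():
    cfg = _cfg(
        cohort_size=50,
        incidence=ZERO_INCIDENCE,
        test=ScreeningTest(specificity=1.0),  # no false positives either
    )
    res = simulate_cohort(cfg, trace=True)
    assert res.screening.treatment_years == 0.0
    assert res.screening.n_recommended == 0
    assert res.no_screening.ad_cases == res.screening.ad_cases == 0
    assert res.no_screening.ad_free_years == res.screening.ad_free_years


def test_crn_identity_zero_effectiveness_arms_match_patientwise():
    cfg = _cfg(treatment=TreatmentPlan(effectiveness=0.0))
    res = simulate_cohort(cfg, trace=True)
    tr = res.trace
    ns = tr[tr.arm == "no_screening"].set_index("id")
    sc = tr[tr.arm == "screening"].set_index("id")
    assert np.array_equal(ns.ad_free_years.to_numpy(), sc.ad_free_years.to_numpy())
    assert res.cases_avoided == 0


def test_screening_arm_never_loses_ad_free_years():
    res = simulate_cohort(_cfg(), trace=True)
    tr = res.trace
    ns = tr[tr.arm == "no_screening"].sort_values("id")
    sc = tr[tr.arm == "screening"].sort_values("id")
    assert np.all(sc.ad_free_years.to_numpy() >= ns.ad_free_years.to_numpy() - 1e-12)


def test_every_avoided_case_was_treated_and_pushed_past_death_or_cap():
    res = simulate_cohort(_cfg(cohort_size=5000), trace=True)
    tr = res.trace
    ns = tr[tr.arm == "no_screening"].set_index("id")
    sc = tr[tr.arm == "screening"].set_index("id")
    avoided = ns.index[ns.realized_onset_age.notna() & sc.realized_onset_age.isna()]
    assert len(avoided) > 0
    for pid in avoided:
        row = sc.loc[pid]
        assert row.treatment_start_age is not None and not math.isnan(row.treatment_start_age)
        # scheduled onset existed but no realized onset: pushed past death/cap
        assert row.scheduled_onset_age < min(row.death_age, 100.0)


def test_seed_reproducibility_is_bit_exact():
    a = simulate_cohort(_cfg(cohort_size=500))
    b = simulate_cohort(_cfg(cohort_size=500))
    assert a.no_screening == b.no_screening
    assert a.screening == b.screening
    assert a.incremental_ad_free_years == b.incremental_ad_free_years


def test_single_patient_cohort_equals_simulate_patient():
    cfg = _cfg(cohort_size=1)
    res = simulate_cohort(cfg, trace=True)
    ns, sc = simulate_patient(cfg, 0)
    assert res.no_screening.ad_free_years == ns.ad_free_years
    assert res.screening.ad_free_years == sc.ad_free_years
    assert res.screening.treatment_years == sc.treatment_years


def test_patient_draws_stable_across_cohort_sizes():
    cfg_small = _cfg(cohort_size=10)
    cfg_big = _cfg(cohort_size=200)
    for pid in (0, 5, 9):
        a = simulate_patient(cfg_small, pid)
        b = simulate_patient(cfg_big, pid)
        assert a == b


def test_recommended_count_matches_binomial_mean_when_rates_coincide():
    """sensitivity == 1 - specificity makes every screen positive with the
    same probability p regardless of truth: recommended ~ Binomial(n, p)."""
    p = 0.3
    cfg = _cfg(cohort_size=4000, test=ScreeningTest(sensitivity=p, specificity=1 - p))
    res = simulate_cohort(cfg)
    n_eligible = 4000  # everyone is alive at the first screen (entry age)
    tol = 4 * math.sqrt(n_eligible * p * (1 - p))
    assert abs(res.screening.n_recommended - n_eligible * p) <= tol


def test_no_screen_arm_matches_analytic_oracles():
    cfg = _cfg(cohort_size=30_000)
    res = simulate_cohort(cfg)
    mean_adfy = res.no_screening.ad_free_years / cfg.cohort_size
    case_p = res.no_screening.ad_cases / cfg.cohort_size
    adfy_expected = analytic_ad_free_years(cfg)
    case_expected = analytic_case_probability(cfg)
    assert mean_adfy == pytest.approx(adfy_expected, abs=0.15)  # ~4 MC sd
    assert case_p == pytest.approx(
        case_expected, abs=4 * math.sqrt(case_expected * (1 - case_expected) / cfg.cohort_size)
    )


def test_discounting_shrinks_years_and_vanishes_at_zero_rate():
    plain = simulate_cohort(_cfg(cohort_size=300))
    disc = simulate_cohort(_cfg(cohort_size=300, discounting_enabled=True))
    zero = simulate_cohort(_cfg(cohort_size=300, discounting_enabled=True, discount_rate=0.0))
    assert disc.no_screening.ad_free_years < plain.no_screening.ad_free_years
    assert zero.no_screening.ad_free_years == pytest.approx(plain.no_screening.ad_free_years)


def test_unending_persistence_treats_until_onset_death_or_cap():
    cfg = _cfg(
        cohort_size=800,
        treatment=TreatmentPlan(persistence=PERSISTENCE_PRESETS["unending"]),
    )
    res = simulate_cohort(cfg, trace=True)
    sc = res.trace[res.trace.arm == "screening"]
    treated = sc[sc.treatment_start_age.notna()]
    end = np.minimum(
        np.where(
            treated.realized_onset_age.notna(), treated.realized_onset_age, np.inf
        ),
        np.minimum(treated.death_age, 100.0),
    )
    np.testing.assert_allclose(
        treated.treatment_years.to_numpy(),
        np.maximum(0.0, end - treated.treatment_start_age.to_numpy()),
        atol=1e-9,
    )


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(cohort_size=0)
    with pytest.raises(ValueError):
        SimulationConfig(pct_male=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(test=ScreeningTest(first_screen_age=101.0))


def test_screen_trace_rows_match_policy():
    cfg = _cfg(cohort_size=400)
    res = simulate_cohort(cfg, trace=True)
    st = res.screen_trace
    # single-screen policy: at most one row per patient, all at the entry age
    assert st.id.is_unique
    assert set(st.screen_age) == {70.0}
    assert (st.result == "positive").sum() == res.screening.n_recommended
    assert set(st.truth) <= {"onset_within_window", "onset_beyond_window_or_never"}
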