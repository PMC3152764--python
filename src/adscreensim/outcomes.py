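"""Cohort comparison statistics: the eight headline outcomes.

Per-1000 normalization and display rounding happen here, at the reporting
edge; NNS and NNT are computed on raw counts before any rounding (hence an
NNS of 51 can coexist with "20 cases avoided per 1000").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .engine import ArmTotals, CohortResult

__all__ = ["CohortComparison", "compare_arms", "compare_result", "comparison_table"]


@dataclass(frozen=True)
class CohortComparison:
    """Per-1000-screened outcomes for a paired run, plus ratio statistics.

    ``nns``/``nnt`` are ``None`` when no cases were avoided — the ratios are
    undefined, not infinite.  ``avoider_share`` is the fraction of the
    incremental AD-free years gained by patients whose onset was pushed past
    death or the age cap.
    """

    n_screened: int
    ad_free_years_no_screening: float
    ad_free_years_screening: float
    ad_free_years_incremental: float
    ad_cases_no_screening: float
    ad_cases_screening: float
    ad_cases_avoided: float
    treatment_years: float
    n_recommended: float
    nns: float | None
    nnt: float | None
    adfy_per_treatment_year: float
    cases_avoided_per_treatment_year: float
    avoider_share: float = math.nan


def compare_arms(
    no_screening: ArmTotals,
    screening: ArmTotals,
    n_screened: int,
    incremental_ad_free_years_avoiders: float = math.nan,
) -> CohortComparison:
    """Reduce paired arm totals to the per-1000 comparison statistics."""
    if no_screening.n != screening.n or no_screening.n != n_screened:
        raise ValueError("arm totals must come from the same paired run")
    k = 1000.0 / n_screened
    avoided_raw = no_screening.ad_cases - screening.ad_cases
    incr_raw = screening.ad_free_years - no_screening.ad_free_years
    ty_raw = screening.treatment_years

    nns = nnt = None
    if avoided_raw > 0:
        nns = n_screened / avoided_raw
        nnt = screening.n_recommended / avoided_raw

    share = math.nan
    if incr_raw > 0 and not math.isnan(incremental_ad_free_years_avoiders):
        share = incremental_ad_free_years_avoiders / incr_raw

    return CohortComparison(
        n_screened=n_screened,
        ad_free_years_no_screening=no_screening.ad_free_years * k,
        ad_free_years_screening=screening.ad_free_years * k,
        ad_free_years_incremental=incr_raw * k,
        ad_cases_no_screening=no_screening.ad_cases * k,
        ad_cases_screening=screening.ad_cases * k,
        ad_cases_avoided=avoided_raw * k,
        treatment_years=ty_raw * k,
        n_recommended=screening.n_recommended * k,
        nns=nns,
        nnt=nnt,
        adfy_per_treatment_year=incr_raw / ty_raw if ty_raw > 0 else math.nan,
        cases_avoided_per_treatment_year=avoided_raw / ty_raw if ty_raw > 0 else math.nan,
        avoider_share=share,
    )


def compare_result(result: CohortResult) -> CohortComparison:
    """Convenience: comparison straight from a ``simulate_cohort`` result."""
    return compare_arms(
        result.no_screening,
        result.screening,
        result.no_screening.n,
        result.incremental_ad_free_years_avoiders,
    )


def comparison_table(cmp: CohortComparison) -> pd.DataFrame:
    """Display table: integer counts/years totals, 4-decimal ratios."""

    def r0(x: float) -> object:
        return round(x) if math.isfinite(x) else None

    rows = [
        ("AD Free Years", r0(cmp.ad_free_years_no_screening),
         r0(cmp.ad_free_years_screening), r0(cmp.ad_free_years_incremental)),
        ("AD Cases", r0(cmp.ad_cases_no_screening), r0(cmp.ad_cases_screening),
         r0(-cmp.ad_cases_avoided)),
        ("Total Years of Treatment", 0, r0(cmp.treatment_years), r0(cmp.treatment_years)),
        ("Number Recommended for Tx", 0, r0(cmp.n_recommended), r0(cmp.n_recommended)),
        ("NNS to Prevent 1 AD Case", None, None,
         r0(cmp.nns) if cmp.nns is not None else "undefined"),
        ("NNT to Prevent 1 AD Case", None, None,
         r0(cmp.nnt) if cmp.nnt is not None else "undefined"),
        ("AD-FY Gain/Person Yr of Treatment", None, None,
         round(cmp.adfy_per_treatment_year, 4)),
        ("AD Case Avoided/Person Yr of Treatment", None, None,
         round(cmp.cases_avoided_per_treatment_year, 4)),
    ]
    return pd.DataFrame(rows, columns=["Outcome (per 1000 screened)", "No Screening",
                                       "Screening", "Incremental"])
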