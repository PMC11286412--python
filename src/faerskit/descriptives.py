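"""Descriptive tabulations of a cleaned report set.

Reproduces the standard clinical-characteristics table of a case series:
sex / age-band / reporter-occupation composition with percentages, report
counts by year and by reporter country, and the distribution of the most
severe outcome per report.  Percentages are recomputed from counts as
100·count/total and rounded half-up to one decimal; every tabulation,
missing-value strata included, sums to the dataset total.

Age bands are <18, 18–60 meaning [18, 60), and ≥60 (the half-open
convention resolves the boundary at 60).
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from ._util import round_half_up
from .clean import SEVERITY_ORDER, most_severe_outcome
from .records import OCCUPATION_CODES, ReportRecord, SEX_CODES

logger = logging.getLogger(__name__)

AGE_BANDS = ("<18", "18-60", ">=60", "NA")


def age_band(age_years: float | None) -> str:
    if age_years is None:
        return "NA"
    if age_years < 18:
        return "<18"
    if age_years < 60:
        return "18-60"
    return ">=60"


def _tabulate(values: Sequence[str], order: Sequence[str], variable: str, total: int) -> pd.DataFrame:
    counts = pd.Series(values).value_counts()
    rows = [
        {
            "variable": variable,
            "stratum": s,
            "count": int(counts.get(s, 0)),
            "percent": round_half_up(100 * counts.get(s, 0) / total, 1) if total else 0.0,
        }
        for s in order
    ]
    return pd.DataFrame(rows)


def summarize_demographics(records: Sequence[ReportRecord]) -> pd.DataFrame:
    """Sex, age-band and occupation composition with 1-decimal percents.

    Columns: variable, stratum, count, percent.  Within each variable the
    counts sum to the dataset total (NA strata included).  Empty input
    yields an empty frame with a warning.
    """
    if not records:
        logger.warning("summarize_demographics: empty dataset")
        return pd.DataFrame(columns=["variable", "stratum", "count", "percent"])
    total = len(records)
    parts = [
        _tabulate([r.sex for r in records], SEX_CODES, "sex", total),
        _tabulate([age_band(r.age_years) for r in records], AGE_BANDS, "age", total),
        _tabulate([r.occupation for r in records], OCCUPATION_CODES, "occupation", total),
    ]
    return pd.concat(parts, ignore_index=True)


def counts_by_year(records: Sequence[ReportRecord]) -> dict[int | str, int]:
    """Report counts per receipt year; undated records count under "NA"."""
    out: dict[int | str, int] = {}
    for r in records:
        key: int | str = r.receipt_date.year if r.receipt_date else "NA"
        out[key] = out.get(key, 0) + 1
    return dict(sorted(out.items(), key=lambda kv: (isinstance(kv[0], str), kv[0])))


def counts_by_country(records: Sequence[ReportRecord]) -> pd.DataFrame:
    """Reporter-country ranking: columns country, count, percent (desc)."""
    total = len(records)
    counts = pd.Series([r.country for r in records]).value_counts()
    return pd.DataFrame(
        {
            "country": counts.index,
            "count": counts.values,
            "percent": [round_half_up(100 * c / total, 1) for c in counts.values],
        }
    )


def outcome_distribution(records: Sequence[ReportRecord]) -> pd.DataFrame:
    """Distribution of the most severe outcome per report.

    Each report is first reduced to its single most severe outcome code
    (death > life-threatening > hospitalization > disability > congenital
    anomaly > required intervention > other; no outcomes → NA), then
    tabulated.  Columns: outcome, count, percent.
    """
    total = len(records)
    reduced = [most_severe_outcome(r.outcomes) for r in records]
    return _tabulate(reduced, list(SEVERITY_ORDER) + ["NA"], "outcome", total).rename(
        columns={"stratum": "outcome"}
    )[["outcome", "count", "percent"]]
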