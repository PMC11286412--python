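"""Disproportionality statistics on the drug × event four-fold table.

For one target drug D and one target event E, every unique report in the
database falls into exactly one cell of the 2×2 table

    ================  ===========  ================
    .                 event E      other events
    ================  ===========  ================
    drug D            a            b
    other drugs       c            d
    ================  ===========  ================

with N = a+b+c+d.  Two classical signal-detection statistics are computed:

* the reporting odds ratio ROR = (a·d)/(b·c) with Wald 95% CI
  exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d)),
* the proportional reporting ratio PRR = [a/(a+b)] / [c/(c+d)] with the
  continuity-corrected chi-square
  χ² = (|ad − bc| − N/2)² · N / [(a+b)(c+d)(a+c)(b+d)].

A drug–event pair is called a signal when a ≥ 3 and at least one criterion
holds: ROR CI lower bound > 1, or PRR ≥ 2 with χ² ≥ 4.

Counting is report-level: a report naming the drug twice still contributes a
single count, and a multi-drug report contributes to the `a` cell of every
drug it names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from ._util import fold
from .records import ReportRecord

Z_95 = 1.96  # normal quantile for the two-sided 95% CI

ZeroCellPolicy = Literal["undefined", "haldane"]


@dataclass(frozen=True)
class FourFoldTable:
    """a/b/c/d report counts for one drug (or category) × one event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_total(self) -> int:
        return self.a + self.b

    @property
    def event_total(self) -> int:
        return self.a + self.c

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class RORResult:
    """Reporting odds ratio with 95% CI; ``defined`` is False for zero cells
    under the default policy (the ratio ad/bc is then degenerate)."""

    ror: float
    ci_lower: float
    ci_upper: float
    se_log: float
    defined: bool


@dataclass(frozen=True)
class PRRResult:
    """Proportional reporting ratio with continuity-corrected chi-square."""

    prr: float
    chi2: float
    defined: bool


@dataclass(frozen=True)
class SignalDecision:
    """Per-drug verdict: a ≥ 3 and (ROR criterion or PRR criterion)."""

    drug: str
    event: str
    a: int
    ror_criterion_met: bool
    prr_criterion_met: bool

    @property
    def signal(self) -> bool:
        return self.ror_criterion_met or self.prr_criterion_met


def _event_mask(records: Sequence[ReportRecord], event: str) -> list[bool]:
    from .clean import match_event

    return [match_event(r, event) for r in records]


def build_contingency(records: Sequence[ReportRecord], drug: str, event: str) -> FourFoldTable:
    """Count the four-fold table for one drug and one event PT.

    The counting unit is the unique report: a report naming the drug in
    several entries counts once.  A drug absent from the dataset yields a
    valid table with a+b = 0.
    """
    target = fold(drug)
    a = b = c = d = 0
    for rec, has_event in zip(records, _event_mask(records, event)):
        has_drug = any(fold(k) == target for k in rec.drug_keys())
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return FourFoldTable(a, b, c, d)


def compute_ror(table: FourFoldTable, zero_cells: ZeroCellPolicy = "undefined") -> RORResult:
    """Reporting odds ratio with Wald 95% CI on the log scale.

    With any zero cell the ratio ad/bc is degenerate; the default policy
    reports ``defined=False`` (the a ≥ 3 signal gate makes a = 0 moot).  The
    Haldane–Anscombe policy instead adds 0.5 to every cell.
    """
    a, b, c, d = (float(x) for x in table.cells())
    if min(a, b, c, d) == 0:
        if zero_cells == "undefined":
            return RORResult(math.nan, math.nan, math.nan, math.nan, defined=False)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return RORResult(
        ror=ror,
        ci_lower=math.exp(log_ror - Z_95 * se),
        ci_upper=math.exp(log_ror + Z_95 * se),
        se_log=se,
        defined=True,
    )


def compute_prr(table: FourFoldTable) -> PRRResult:
    """Proportional reporting ratio and Yates-corrected chi-square.

    Undefined when the drug row is empty (a+b = 0), the comparator row is
    empty (c+d = 0), or c = 0 (the comparator event proportion vanishes).
    The chi-square clamps to 0 when the continuity correction overshoots
    (|ad − bc| ≤ N/2): a squared corrected statistic cannot be negative.
    """
    a, b, c, d = table.cells()
    n = table.n
    if a + b == 0 or c + d == 0 or c == 0:
        return PRRResult(math.nan, math.nan, defined=False)
    prr = (a / (a + b)) / (c / (c + d))
    diff = abs(a * d - b * c)
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if diff <= n / 2 or margins == 0:
        chi2 = 0.0
    else:
        chi2 = (diff - n / 2) ** 2 * n / margins
    return PRRResult(prr=prr, chi2=chi2, defined=True)


def evaluate_signal(
    table: FourFoldTable,
    ror: RORResult,
    prr: PRRResult,
    drug: str = "",
    event: str = "",
    min_reports: int = 3,
) -> SignalDecision:
    """Combine both criteria: signal iff a ≥ min_reports and (ROR CI lower
    bound > 1, or PRR ≥ 2 with χ² ≥ 4)."""
    enough = table.a >= min_reports
    ror_met = enough and ror.defined and ror.ci_lower > 1
    prr_met = enough and prr.defined and prr.prr >= 2 and prr.chi2 >= 4
    return SignalDecision(
        drug=drug, event=event, a=table.a, ror_criterion_met=ror_met, prr_criterion_met=prr_met
    )


def point_from_ci(ci_lower: float, ci_upper: float) -> float:
    """Recover the point estimate from a log-symmetric 95% CI.

    A Wald interval on the log scale is symmetric about ln(estimate), so the
    point estimate is the geometric mean of its bounds,
    exp[(ln L + ln U)/2] = sqrt(L·U).
    """
    if ci_lower <= 0 or ci_upper <= 0:
        raise ValueError("CI bounds must be positive")
    if ci_lower > ci_upper:
        raise ValueError("ci_lower must not exceed ci_upper")
    return math.exp((math.log(ci_lower) + math.log(ci_upper)) / 2)


@dataclass(frozen=True)
class DrugScreenRow:
    """One row of a screening run: a drug with its full statistics."""

    drug: str
    table: FourFoldTable
    ror: RORResult
    prr: PRRResult
    decision: SignalDecision


def screen(
    records: Sequence[ReportRecord],
    event: str,
    min_reports: int = 3,
    top_n: int | None = 30,
    zero_cells: ZeroCellPolicy = "undefined",
    drugs: Iterable[str] | None = None,
) -> list[DrugScreenRow]:
    """Screen drugs against one event, ranked by report count.

    Drugs are ranked by the `a` cell (descending, name ascending on ties) and
    the top ``top_n`` retained; pass ``top_n=None`` to keep all, or ``drugs``
    to restrict the candidate set.  Signal-strength ordering (ROR descending)
    is available by sorting the returned rows.
    """
    mask = _event_mask(records, event)
    a_counts: dict[str, int] = {}
    drug_totals: dict[str, int] = {}
    for rec, has_event in zip(records, mask):
        for key in rec.drug_keys():
            drug_totals[key] = drug_totals.get(key, 0) + 1
            if has_event:
                a_counts[key] = a_counts.get(key, 0) + 1
    if drugs is not None:
        wanted = {fold(d) for d in drugs}
        drug_totals = {k: v for k, v in drug_totals.items() if fold(k) in wanted}
    n_total = len(records)
    n_event = sum(mask)
    ranked = sorted(drug_totals, key=lambda k: (-a_counts.get(k, 0), k))
    if top_n is not None:
        ranked = ranked[:top_n]
    rows = []
    for drug in ranked:
        a = a_counts.get(drug, 0)
        b = drug_totals[drug] - a
        c = n_event - a
        d = n_total - n_event - b
        table = FourFoldTable(a, b, c, d)
        ror = compute_ror(table, zero_cells)
        prr = compute_prr(table)
        rows.append(
            DrugScreenRow(
                drug=drug,
                table=table,
                ror=ror,
                prr=prr,
                decision=evaluate_signal(table, ror, prr, drug, event, min_reports),
            )
        )
    return rows
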