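"""Model/Results interface over the disproportionality pipeline.

:class:`DisproportionalityModel` is built from a set of spontaneous reports
(optionally cleaning them on construction) and one target event;
``fit()`` screens drugs — and, given a category map, therapeutic
categories — returning a :class:`DisproportionalityResults` with the
four-fold counts, ROR/PRR estimates, confidence intervals and signal calls,
plus ``summary()`` and export/plot helpers.

    >>> model = DisproportionalityModel(records, event_pt="Angioedema")
    >>> res = model.fit(top_n=30, category_map=CategoryMap.default())
    >>> print(res.summary())
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import round_half_up
from .categories import CategoryMap, rollup
from .clean import CleaningReport, SynonymMap, clean, match_event
from .contingency import DrugScreenRow, ZeroCellPolicy, screen
from .records import Dialect, ReportRecord, read_reports


def rows_to_frame(rows: Sequence[DrugScreenRow]) -> pd.DataFrame:
    """Screening rows as a DataFrame (full precision, one row per drug)."""
    return pd.DataFrame(
        {
            "drug": [r.drug for r in rows],
            "a": [r.table.a for r in rows],
            "b": [r.table.b for r in rows],
            "c": [r.table.c for r in rows],
            "d": [r.table.d for r in rows],
            "ror": [r.ror.ror for r in rows],
            "ci_lower": [r.ror.ci_lower for r in rows],
            "ci_upper": [r.ror.ci_upper for r in rows],
            "prr": [r.prr.prr for r in rows],
            "chi2": [r.prr.chi2 for r in rows],
            "ror_criterion": [r.decision.ror_criterion_met for r in rows],
            "prr_criterion": [r.decision.prr_criterion_met for r in rows],
            "signal": [r.decision.signal for r in rows],
        }
    )


class DisproportionalityResults:
    """Estimates from one screening run.

    Attributes
    ----------
    per_drug : pandas.DataFrame
        One row per screened drug: cells a–d, ROR with 95% CI, PRR with χ²,
        and the signal verdict (a ≥ 3 and either criterion).
    per_category : pandas.DataFrame or None
        Same shape at therapeutic-category level, when a map was given.
    cleaning : CleaningReport or None
        Stage counts when the model cleaned its input.
    """

    def __init__(
        self,
        model: "DisproportionalityModel",
        drug_rows: list[DrugScreenRow],
        category_rows: list[DrugScreenRow] | None,
    ) -> None:
        self.model = model
        self.drug_rows = drug_rows
        self.category_rows = category_rows
        self.per_drug = rows_to_frame(drug_rows)
        self.per_category = rows_to_frame(category_rows) if category_rows is not None else None
        self.cleaning = model.cleaning

    @property
    def n_signals(self) -> int:
        return int(self.per_drug["signal"].sum())

    def by_signal_strength(self) -> pd.DataFrame:
        """Per-drug rows reordered by ROR descending (undefined last)."""
        return self.per_drug.sort_values(
            "ror", ascending=False, na_position="last", kind="mergesort"
        ).reset_index(drop=True)

    def _display(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in ("ror", "ci_lower", "ci_upper", "prr"):
            out[col] = out[col].map(lambda x: round_half_up(x, 2) if pd.notna(x) else x)
        out["chi2"] = out["chi2"].map(lambda x: round_half_up(x, 1) if pd.notna(x) else x)
        return out

    def summary(self) -> str:
        """Plain-text summary table, display-rounded (half-up, 2 decimals)."""
        m = self.model
        lines = [
            "Disproportionality screening results",
            "=" * 68,
            f"Event PT:        {m.event_pt}",
            f"Reports (N):     {len(m.records)}",
            f"Event reports:   {m.n_event_reports}",
            f"Signal rule:     a >= {m.min_reports} and (ROR CI low > 1  or  PRR >= 2 & chi2 >= 4)",
            f"Signals found:   {self.n_signals} / {len(self.per_drug)} drugs screened",
            "-" * 68,
            self._display(self.per_drug).to_string(index=False),
        ]
        if self.per_category is not None:
            lines += [
                "-" * 68,
                "Therapeutic categories",
                self._display(self.per_category).to_string(index=False),
            ]
        return "\n".join(lines)

    def to_csv(self, drug_path: str | Path, category_path: str | Path | None = None) -> None:
        """Export per-drug (and optionally per-category) tables as CSV."""
        cols = ["drug", "a", "b", "c", "d", "ror", "ci_lower", "ci_upper", "prr", "chi2", "signal"]
        self.per_drug[cols].to_csv(drug_path, index=False)
        if category_path is not None and self.per_category is not None:
            self.per_category[cols].to_csv(category_path, index=False)

    def plot_forest(self, which: str = "drug", ax=None):
        """Forest plot of ROR with 95% CI (log scale); see plotting module."""
        from .plotting import plot_forest

        df = self.per_category if which == "category" else self.per_drug
        if df is None:
            raise ValueError("no category results on this fit")
        return plot_forest(df, ax=ax)


class DisproportionalityModel:
    """Drug–event disproportionality screen over spontaneous reports.

    Parameters
    ----------
    records : sequence of ReportRecord
        The report database (all reports, with and without the event — the
        non-event reports populate the b and d cells).
    event_pt : str
        Target MedDRA preferred term, matched exactly (case-insensitive).
    min_reports : int
        Minimum `a` for a signal (default 3).
    zero_cells : {"undefined", "haldane"}
        Policy for zero cells in the ROR (default leaves it undefined).
    clean_input : bool
        When True, run standardize → deduplicate → exclude on construction.
    """

    def __init__(
        self,
        records: Sequence[ReportRecord],
        event_pt: str = "Angioedema",
        min_reports: int = 3,
        zero_cells: ZeroCellPolicy = "undefined",
        clean_input: bool = False,
        synonym_map: SynonymMap | None = None,
        exclusion_list: Iterable[str] = (),
    ) -> None:
        self.event_pt = event_pt
        self.min_reports = min_reports
        self.zero_cells: ZeroCellPolicy = zero_cells
        self.cleaning: CleaningReport | None = None
        if clean_input:
            cleaned, self.cleaning = clean(
                records, synonym_map=synonym_map, exclusion_list=exclusion_list, event_pt=event_pt
            )
            self.records: list[ReportRecord] = cleaned
        else:
            self.records = list(records)
        self.n_event_reports = sum(match_event(r, event_pt) for r in self.records)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        dialect: Dialect = Dialect(),
        **kwargs,
    ) -> "DisproportionalityModel":
        """Build from a long-format report file (see the records module)."""
        return cls(read_reports(path, dialect), **kwargs)

    def fit(
        self,
        top_n: int | None = 30,
        category_map: CategoryMap | None = None,
        drugs: Iterable[str] | None = None,
    ) -> DisproportionalityResults:
        """Screen the ``top_n`` drugs by report count (and categories if a
        map is supplied) and return the results object."""
        drug_rows = screen(
            self.records,
            self.event_pt,
            min_reports=self.min_reports,
            top_n=top_n,
            zero_cells=self.zero_cells,
            drugs=drugs,
        )
        cat_rows = None
        if category_map is not None:
            cat_rows = rollup(
                self.records,
                category_map,
                self.event_pt,
                min_reports=self.min_reports,
                zero_cells=self.zero_cells,
            )
        return DisproportionalityResults(self, drug_rows, cat_rows)
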