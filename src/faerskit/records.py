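"""Report data structures and delimited-file I/O.

A spontaneous adverse-event report links one patient case to one or more
drugs, one or more MedDRA preferred-term (PT) reactions, and zero or more
seriousness outcome codes.  Datasets are stored in a single long-format
CSV/TSV: one report spans as many rows as ``max(len(drugs), len(reactions))``,
rows beyond a list's length leaving that column empty; scalar fields repeat
on every row.  This mirrors the DEMO/DRUG/REAC/OUTC split of the FDA Adverse
Event Reporting System (FAERS) without requiring four files.

Missing values are written as empty strings and surfaced as ``None`` (scalar
fields) or the string code ``"NA"`` where a categorical vocabulary defines
one.  Dates are ISO-8601 (``YYYY-MM-DD``).
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: FAERS seriousness outcome codes: death, life-threatening, hospitalization,
#: disability, congenital anomaly, required intervention, other.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

SEX_CODES = ("F", "M", "OTHER", "NA")
OCCUPATION_CODES = ("CONSUMER", "HEALTH_PROFESSIONAL", "OTHER", "NA")

#: Column schema of the long-format report file, in order.
COLUMNS = (
    "report_id",
    "case_id",
    "receipt_date",
    "age_years",
    "sex",
    "occupation",
    "country",
    "drug_verbatim",
    "drug_standardized",
    "is_combination",
    "reaction_pt",
    "outcome_codes",
)


@dataclass(frozen=True)
class Dialect:
    """Delimiter/quoting configuration for report files."""

    delimiter: str = ","
    quotechar: str = '"'

    @classmethod
    def csv(cls) -> "Dialect":
        return cls(",")

    @classmethod
    def tsv(cls) -> "Dialect":
        return cls("\t")

    @classmethod
    def faers_ascii(cls) -> "Dialect":
        """Preset for FAERS quarterly ASCII extracts ($-delimited).

        Only the delimiter convention is provided; the full native FAERS
        schema is not guaranteed — files must still carry this package's
        column header.
        """
        return cls("$")


@dataclass
class DrugEntry:
    """One drug mention within a report.

    ``standardized_name`` is the generic name assigned by synonym lookup;
    ``None`` until standardization, after which unresolved verbatim names
    remain ``None`` with the record retained.  Combination products (more
    than one active ingredient) keep a single combined identity.
    """

    verbatim_name: str
    standardized_name: str | None = None
    is_combination: bool = False

    @property
    def resolved(self) -> bool:
        return self.standardized_name is not None

    def key(self) -> str:
        """Identity used for counting/dedup: standardized name, else folded verbatim."""
        from ._util import fold

        return self.standardized_name if self.standardized_name is not None else fold(self.verbatim_name)


@dataclass
class ReportRecord:
    """One cleaned spontaneous report.

    ``report_id`` is unique per record after cleaning; ``case_id`` is the
    patient/case identifier shared by duplicate submissions of the same case.
    """

    report_id: str
    case_id: str
    receipt_date: _dt.date | None
    age_years: float | None
    sex: str
    occupation: str
    country: str
    drugs: list[DrugEntry]
    reactions: list[str]
    outcomes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError(f"report {self.report_id}: drugs must be non-empty")
        if not self.reactions:
            raise ValueError(f"report {self.report_id}: reactions must be non-empty")
        if self.age_years is not None and not (0 <= self.age_years <= 150):
            raise ValueError(f"report {self.report_id}: age {self.age_years} outside [0, 150]")
        if self.sex not in SEX_CODES:
            raise ValueError(f"report {self.report_id}: bad sex code {self.sex!r}")
        if self.occupation not in OCCUPATION_CODES:
            raise ValueError(f"report {self.report_id}: bad occupation code {self.occupation!r}")
        for code in self.outcomes:
            if code not in OUTCOME_CODES:
                raise ValueError(f"report {self.report_id}: bad outcome code {code!r}")

    def drug_keys(self) -> frozenset[str]:
        """Set of drug identities named by this report (unique-report counting unit)."""
        return frozenset(d.key() for d in self.drugs)

    def copy(self) -> "ReportRecord":
        return replace(
            self,
            drugs=[replace(d) for d in self.drugs],
            reactions=list(self.reactions),
            outcomes=list(self.outcomes),
        )


class SchemaError(ValueError):
    """Raised when an input file lacks mandatory columns."""


def _parse_date(s: str) -> _dt.date | None:
    if not s:
        return None
    return _dt.date.fromisoformat(s)


def read_reports(path: str | Path, dialect: Dialect = Dialect()) -> list[ReportRecord]:
    """Read a long-format report file into :class:`ReportRecord` objects.

    Rows sharing a ``report_id`` are merged: drug and reaction cells
    accumulate positionally, outcome codes are taken from the first row.
    Malformed rows (e.g. unparseable dates) are counted and logged, never
    silently dropped: the offending field is set missing and the record
    flagged in the log.

    Raises
    ------
    SchemaError
        If mandatory columns are absent, naming the missing ones.
    """
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        quotechar=dialect.quotechar,
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")

    records: list[ReportRecord] = []
    n_flagged = 0
    # groupby(sort=False) preserves first-appearance order → deterministic reads.
    for report_id, group in df.groupby("report_id", sort=False):
        first = group.iloc[0]
        try:
            date = _parse_date(first["receipt_date"])
        except ValueError:
            logger.warning("report %s: unparseable date %r set missing", report_id, first["receipt_date"])
            n_flagged += 1
            date = None
        age = float(first["age_years"]) if first["age_years"] else None
        drugs = [
            DrugEntry(
                verbatim_name=row["drug_verbatim"],
                standardized_name=row["drug_standardized"] or None,
                is_combination=row["is_combination"] == "1",
            )
            for _, row in group.iterrows()
            if row["drug_verbatim"]
        ]
        reactions = [row["reaction_pt"] for _, row in group.iterrows() if row["reaction_pt"]]
        outcomes = first["outcome_codes"].split() if first["outcome_codes"] else []
        records.append(
            ReportRecord(
                report_id=str(report_id),
                case_id=first["case_id"],
                receipt_date=date,
                age_years=age,
                sex=first["sex"] or "NA",
                occupation=first["occupation"] or "NA",
                country=first["country"] or "NA",
                drugs=drugs,
                reactions=reactions,
                outcomes=outcomes,
            )
        )
    if n_flagged:
        logger.warning("%d malformed rows flagged while reading %s", n_flagged, path)
    return records


def write_reports(records: Iterable[ReportRecord], path: str | Path, dialect: Dialect = Dialect()) -> None:
    """Write records to a long-format file; inverse of :func:`read_reports`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, quotechar=dialect.quotechar)
        writer.writerow(COLUMNS)
        for rec in records:
            n_rows = max(len(rec.drugs), len(rec.reactions))
            outcome_str = " ".join(rec.outcomes)
            for i in range(n_rows):
                drug = rec.drugs[i] if i < len(rec.drugs) else None
                writer.writerow(
                    [
                        rec.report_id,
                        rec.case_id,
                        rec.receipt_date.isoformat() if rec.receipt_date else "",
                        repr(rec.age_years) if rec.age_years is not None else "",
                        rec.sex,
                        rec.occupation,
                        rec.country,
                        drug.verbatim_name if drug else "",
                        (drug.standardized_name or "") if drug else "",
                        ("1" if drug.is_combination else "0") if drug else "",
                        rec.reactions[i] if i < len(rec.reactions) else "",
                        outcome_str,
                    ]
                )


def to_dataframe(records: Sequence[ReportRecord]) -> pd.DataFrame:
    """One row per report with list-valued drug/reaction/outcome columns."""
    return pd.DataFrame(
        {
            "report_id": [r.report_id for r in records],
            "case_id": [r.case_id for r in records],
            "receipt_date": [r.receipt_date for r in records],
            "age_years": [r.age_years for r in records],
            "sex": [r.sex for r in records],
            "occupation": [r.occupation for r in records],
            "country": [r.country for r in records],
            "drugs": [sorted(r.drug_keys()) for r in records],
            "reactions": [list(r.reactions) for r in records],
            "outcomes": [list(r.outcomes) for r in records],
        }
    )
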