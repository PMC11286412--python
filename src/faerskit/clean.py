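"""Report cleaning: duplicate removal, name standardization, exclusions,
event matching and most-severe-outcome reduction.

Spontaneous-report databases accumulate duplicate submissions (follow-up
versions of the same case) and free-text drug names.  Cleaning proceeds:

1. standardize drug names against a user-supplied synonym map,
2. remove duplicates — records identical on (case, date, drug set) collapse
   to one; among several versions of the same (case, drug set) across dates
   only the latest is retained,
3. drop excluded drugs (non-pharmaceuticals, withdrawn products), dropping
   records left drug-less.

Standardization runs first so duplicate keys compare standardized names;
:func:`clean` exposes a switch to reverse the order.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._util import fold
from .records import DrugEntry, ReportRecord

logger = logging.getLogger(__name__)

#: Seriousness ranking used to reduce multiple outcome codes to one, worst
#: first: death > life-threatening > hospitalization > disability >
#: congenital anomaly > required intervention > other.
SEVERITY_ORDER = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
_SEVERITY_RANK = {code: i for i, code in enumerate(SEVERITY_ORDER)}


@dataclass
class SynonymMap:
    """Verbatim→generic drug-name mapping, case-folded on lookup.

    ``combination_flags`` lists standardized names denoting combination
    products (formulations with more than one active ingredient); such
    products keep a single combined identity and are never split.
    """

    entries: dict[str, str] = field(default_factory=dict)
    combination_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        folded: dict[str, str] = {}
        for verbatim, standard in self.entries.items():
            if not standard:
                raise ValueError(f"empty standardized name for {verbatim!r}")
            key = fold(verbatim)
            if key in folded and folded[key] != standard:
                raise ValueError(f"conflicting synonym entries for {verbatim!r}")
            folded[key] = standard
        self.entries = folded

    def lookup(self, verbatim: str) -> str | None:
        return self.entries.get(fold(verbatim))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SynonymMap":
        """Two-column CSV (verbatim,standardized); optional third column
        ``combination`` with 1 flagging combination products."""
        entries: dict[str, str] = {}
        combos: set[str] = set()
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None:
                return cls()
            for row in reader:
                if not row or not row[0]:
                    continue
                entries[row[0]] = row[1]
                if len(row) > 2 and row[2].strip() == "1":
                    combos.add(row[1])
        return cls(entries=entries, combination_flags=combos)


@dataclass
class CleaningReport:
    """Record counts at each pipeline stage (monotone non-increasing)."""

    n_input: int = 0
    n_after_dedup: int = 0
    n_after_exclusion: int = 0
    n_event_matched: int = 0

    def __post_init__(self) -> None:
        if not (self.n_input >= self.n_after_dedup >= self.n_after_exclusion >= 0):
            raise ValueError("pipeline counts must be monotone non-increasing")


def _dedup_sort_key(rec: ReportRecord):
    # Missing dates sort earliest so dated evidence wins latest-retention;
    # report_id breaks exact ties deterministically (greatest survives).
    return (rec.receipt_date is not None, rec.receipt_date or _dt.date.min, rec.report_id)


def deduplicate(records: Sequence[ReportRecord]) -> tuple[list[ReportRecord], CleaningReport]:
    """Remove duplicate and superseded report versions.

    Records are grouped by (case_id, set of drug identities); within a group
    only the record with the latest receipt date survives (missing dates sort
    earliest), ties broken by the lexicographically greatest report_id.  This
    collapses both exact duplicates (same case, date, drugs) and older
    versions of a case's report for the same medication.  Output preserves
    input order of the surviving records; idempotent.
    """
    best: dict[tuple[str, frozenset[str]], ReportRecord] = {}
    for rec in records:
        key = (rec.case_id, rec.drug_keys())
        cur = best.get(key)
        if cur is None or _dedup_sort_key(rec) > _dedup_sort_key(cur):
            best[key] = rec
    keep = {id(r) for r in best.values()}
    out = [r for r in records if id(r) in keep]
    report = CleaningReport(
        n_input=len(records),
        n_after_dedup=len(out),
        n_after_exclusion=len(out),
    )
    if len(out) < len(records):
        logger.info("deduplicate: removed %d of %d records", len(records) - len(out), len(records))
    return out, report


def standardize_drugs(records: Iterable[ReportRecord], synonym_map: SynonymMap) -> list[ReportRecord]:
    """Assign standardized generic names by exact case-insensitive lookup.

    Unresolved names keep their verbatim form (``standardized_name`` stays
    ``None``) and the record is retained; fuzzy matching is out of scope.
    Entries already standardized are left untouched unless the map overrides
    them.  Combination products keep their single combined identity.
    """
    if not synonym_map.entries:
        logger.warning("standardize_drugs: empty synonym map, all lookups unresolved")
    out = []
    n_unresolved = 0
    for rec in records:
        rec = rec.copy()
        for entry in rec.drugs:
            hit = synonym_map.lookup(entry.verbatim_name)
            if hit is not None:
                entry.standardized_name = hit
                if hit in synonym_map.combination_flags:
                    entry.is_combination = True
            elif entry.standardized_name is None:
                n_unresolved += 1
        out.append(rec)
    if n_unresolved:
        logger.info("standardize_drugs: %d drug entries unresolved", n_unresolved)
    return out


def exclude_drugs(
    records: Sequence[ReportRecord], exclusion_list: Iterable[str]
) -> tuple[list[ReportRecord], CleaningReport]:
    """Drop excluded drugs; drop (and count) records left with no drugs."""
    excluded = {fold(name) for name in exclusion_list}
    out: list[ReportRecord] = []
    n_dropped = 0
    for rec in records:
        kept = [d for d in rec.drugs if fold(d.key()) not in excluded]
        if not kept:
            n_dropped += 1
            continue
        if len(kept) != len(rec.drugs):
            rec = rec.copy()
            rec.drugs = [d for d in rec.drugs if fold(d.key()) not in excluded]
        out.append(rec)
    if n_dropped:
        logger.info("exclude_drugs: dropped %d records left with no drugs", n_dropped)
    report = CleaningReport(n_input=len(records), n_after_dedup=len(records), n_after_exclusion=len(out))
    return out, report


def match_event(record: ReportRecord, pt: str) -> bool:
    """True iff any reaction equals the target MedDRA preferred term.

    Matching is exact after case-folding and whitespace normalization — no
    standardised-MedDRA-query expansion, so e.g. "Angioedema hereditary"
    does not match PT "angioedema".
    """
    if not pt:
        raise ValueError("pt must be non-empty")
    target = fold(pt)
    return any(fold(r) == target for r in record.reactions)


def most_severe_outcome(codes: Sequence[str]) -> str:
    """Reduce multiple outcome codes to the most severe one; empty → "NA"."""
    if not codes:
        return "NA"
    return min(codes, key=lambda c: _SEVERITY_RANK[c])


def clean(
    records: Sequence[ReportRecord],
    synonym_map: SynonymMap | None = None,
    exclusion_list: Iterable[str] = (),
    event_pt: str | None = None,
    standardize_before_dedup: bool = True,
) -> tuple[list[ReportRecord], CleaningReport]:
    """Full cleaning pipeline: standardize → deduplicate → exclude.

    ``event_pt`` only fills ``n_event_matched`` in the returned report; the
    cleaned dataset keeps all reports (disproportionality needs the
    non-event reports for the b and d cells).
    """
    n_input = len(records)
    work = list(records)
    if synonym_map is not None and standardize_before_dedup:
        work = standardize_drugs(work, synonym_map)
    work, _ = deduplicate(work)
    if synonym_map is not None and not standardize_before_dedup:
        work = standardize_drugs(work, synonym_map)
    n_after_dedup = len(work)
    work, _ = exclude_drugs(work, exclusion_list)
    report = CleaningReport(
        n_input=n_input,
        n_after_dedup=n_after_dedup,
        n_after_exclusion=len(work),
        n_event_matched=sum(match_event(r, event_pt) for r in work) if event_pt else 0,
    )
    return work, report


def load_exclusion_list(path: str | Path) -> list[str]:
    """One-column CSV of standardized names to exclude (header optional)."""
    names = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or not row[0].strip():
                continue
            if i == 0 and fold(row[0]) in {"drug", "name", "standardized"}:
                continue
            names.append(row[0].strip())
    return names
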