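"""Synthetic spontaneous-report generator with known ground truth.

Emulates a FAERS-like database so that every pipeline stage — I/O, cleaning,
disproportionality, rollup, descriptives — is testable without downloads:

* each report draws its drugs independently from a catalog of marginal
  reporting probabilities (at least one drug enforced by redraw);
* the target event is assigned per report from a logistic odds model: the
  baseline odds (``background_event_rate``) are multiplied by a true odds
  ratio θ for every exposed signal drug, so with a single signal drug the
  population reporting odds ratio equals θ exactly and injected signals are
  recoverable;
* demographics (sex, age band, occupation, country), receipt year and the
  most-severe outcome are drawn i.i.d. from categorical marginals patterned
  on a large angioedema case series (≈47% female, ≈74% adult, ≈73%
  health-professional reporters, years 2004–2023);
* duplicate contamination appends exact copies of randomly chosen reports
  with fresh report_ids but identical case/date/drugs, the duplicate
  definition the cleaning stage targets; the default rate (12%) matches the
  shrinkage of a typical raw extract under deduplication.

All draws flow through one seeded :class:`numpy.random.Generator`, so a
given config is bit-reproducible.  :func:`sample_tables` shares the same
exposure/event core but skips record materialisation, for calibration and
coverage studies that need thousands of simulated databases.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .contingency import FourFoldTable
from .records import DrugEntry, ReportRecord

#: Marginal reporting probability per drug: the 30 drugs screened in the
#: worked angioedema analysis, frequent antihypertensives/analgesics higher.
DEFAULT_DRUG_CATALOG: dict[str, float] = {
    "lisinopril": 0.045,
    "enalapril": 0.020,
    "perindopril": 0.008,
    "alteplase": 0.010,
    "ramipril": 0.025,
    "carbasalate calcium": 0.004,
    "ibuprofen": 0.090,
    "losartan": 0.040,
    "amlodipine": 0.060,
    "hydrochlorothiazide and lisinopril": 0.012,
    "amoxicillin": 0.050,
    "amoxicillin potassium clavulanate combination": 0.020,
    "omalizumab": 0.008,
    "cetirizine": 0.030,
    "clarithromycin": 0.020,
    "valsartan": 0.035,
    "naproxen": 0.040,
    "montelukast": 0.025,
    "paracetamol": 0.110,
    "diclofenac": 0.035,
    "lansoprazole": 0.030,
    "celecoxib": 0.020,
    "sitagliptin phosphate": 0.015,
    "omeprazole": 0.070,
    "pregabalin": 0.045,
    "infliximab": 0.030,
    "secukinumab": 0.012,
    "lenalidomide": 0.025,
    "etanercept": 0.035,
    "adalimumab": 0.060,
}

#: True odds ratios injected by default: strong bradykinin-pathway signals
#: (ACE inhibitors, a fibrinolytic), everything else null.
DEFAULT_DRUG_EVENT_OR: dict[str, float] = {
    "lisinopril": 46.0,
    "enalapril": 43.5,
    "perindopril": 31.2,
    "alteplase": 29.3,
    "ramipril": 20.9,
}

DEFAULT_SEX_MARGINAL = {"F": 0.469, "M": 0.440, "OTHER": 0.008, "NA": 0.083}
DEFAULT_AGE_MARGINAL = {"<18": 0.049, "18-60": 0.376, ">=60": 0.362, "NA": 0.213}
DEFAULT_OCCUPATION_MARGINAL = {
    "CONSUMER": 0.138,
    "HEALTH_PROFESSIONAL": 0.728,
    "OTHER": 0.093,
    "NA": 0.041,
}
DEFAULT_COUNTRY_MARGINAL = {
    "US": 0.45, "FR": 0.09, "GB": 0.08, "CA": 0.06, "IT": 0.05,
    "DE": 0.04, "ES": 0.03, "PT": 0.02, "NA": 0.036, "OTHER": 0.144,
}
#: Most-severe-outcome mixture ("NA" = no outcome codes on the report).
DEFAULT_OUTCOME_MIXTURE = {
    "DE": 0.136, "LT": 0.050, "HO": 0.301, "DS": 0.040,
    "CA": 0.005, "RI": 0.010, "OT": 0.300, "NA": 0.158,
}
#: Reaction PTs used alongside / instead of the target event.
DEFAULT_OTHER_REACTIONS = (
    "Rash", "Urticaria", "Pruritus", "Dyspnoea", "Nausea",
    "Headache", "Dizziness", "Fatigue",
)

_AGE_BOUNDS = {"<18": (0.0, 18.0), "18-60": (18.0, 60.0), ">=60": (60.0, 100.0)}


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate a 2004–2023 angioedema screen."""

    n_reports: int = 2000
    drug_catalog: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRUG_CATALOG))
    event_pt: str = "Angioedema"
    background_event_rate: float = 0.02
    drug_event_or: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRUG_EVENT_OR))
    mean_drugs_per_report: float | None = None
    dup_rate: float = 0.12
    sex_marginal: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_MARGINAL))
    age_marginal: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_MARGINAL))
    occupation_marginal: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OCCUPATION_MARGINAL))
    country_marginal: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUNTRY_MARGINAL))
    year_range: tuple[int, int] = (2004, 2023)
    outcome_mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_MIXTURE))
    extra_outcome_rate: float = 0.3
    extra_reaction_rate: float = 0.5
    other_reactions: tuple[str, ...] = DEFAULT_OTHER_REACTIONS
    seed: int = 42

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if not self.drug_catalog or not any(p > 0 for p in self.drug_catalog.values()):
            raise ValueError("drug_catalog needs at least one positive marginal")
        for name, p in self.drug_catalog.items():
            if not 0 <= p <= 1:
                raise ValueError(f"marginal for {name!r} outside [0, 1]")
        if not 0 < self.background_event_rate < 1:
            raise ValueError("background_event_rate must be in (0, 1)")
        for name, theta in self.drug_event_or.items():
            if theta <= 0:
                raise ValueError(f"odds ratio for {name!r} must be positive")
        if not 0 <= self.dup_rate <= 1:
            raise ValueError("dup_rate must be in [0, 1]")
        for label, marg in (
            ("sex_marginal", self.sex_marginal),
            ("age_marginal", self.age_marginal),
            ("occupation_marginal", self.occupation_marginal),
            ("country_marginal", self.country_marginal),
            ("outcome_mixture", self.outcome_mixture),
        ):
            if not marg or sum(marg.values()) <= 0:
                raise ValueError(f"{label} must have positive total mass")

    @property
    def n_duplicates(self) -> int:
        return math.floor(self.dup_rate * self.n_reports)

    def drug_probs(self) -> tuple[list[str], np.ndarray]:
        names = list(self.drug_catalog)
        probs = np.array([self.drug_catalog[n] for n in names], dtype=float)
        if self.mean_drugs_per_report is not None:
            probs = np.clip(probs * self.mean_drugs_per_report / probs.sum(), 0.0, 1.0)
        return names, probs

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "year_range" in d:
            d["year_range"] = tuple(d["year_range"])
        if "other_reactions" in d:
            d["other_reactions"] = tuple(d["other_reactions"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load from JSON or YAML (by extension)."""
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def _normalized(marg: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    keys = list(marg)
    w = np.array([marg[k] for k in keys], dtype=float)
    return keys, w / w.sum()


def _draw_exposure_events(
    config: SyntheticConfig, rng: np.random.Generator, n: int
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Vectorised exposure matrix (n × drugs) and event indicator vector.

    This is the generative core shared by :func:`generate` and
    :func:`sample_tables`: per-drug Bernoulli exposure (empty rows redrawn),
    then a per-report event from baseline odds multiplied by θ for each
    exposed signal drug.
    """
    names, probs = config.drug_probs()
    exposure = rng.random((n, len(names))) < probs
    while True:
        empty = ~exposure.any(axis=1)
        if not empty.any():
            break
        exposure[empty] = rng.random((int(empty.sum()), len(names))) < probs
    r = config.background_event_rate
    log_theta = np.array([math.log(config.drug_event_or.get(nm, 1.0)) for nm in names])
    log_odds = math.log(r / (1 - r)) + exposure @ log_theta
    event = rng.random(n) < expit(log_odds)
    return names, exposure, event


def generate(config: SyntheticConfig) -> list[ReportRecord]:
    """Generate ``n_reports`` primary reports plus duplicate contamination.

    Returns the primaries followed by ``⌊dup_rate·n⌋`` exact copies of
    randomly chosen primaries carrying fresh report_ids but the same
    case_id, date and drugs — precisely what deduplication must remove.
    Bit-reproducible for a given config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    names, exposure, event = _draw_exposure_events(config, rng, n)

    sex_keys, sex_p = _normalized(config.sex_marginal)
    age_keys, age_p = _normalized(config.age_marginal)
    occ_keys, occ_p = _normalized(config.occupation_marginal)
    cty_keys, cty_p = _normalized(config.country_marginal)
    out_keys, out_p = _normalized(config.outcome_mixture)

    sexes = rng.choice(sex_keys, size=n, p=sex_p)
    bands = rng.choice(age_keys, size=n, p=age_p)
    age_u = rng.random(n)
    occs = rng.choice(occ_keys, size=n, p=occ_p)
    ctys = rng.choice(cty_keys, size=n, p=cty_p)
    y0, y1 = config.year_range
    years = rng.integers(y0, y1 + 1, size=n)
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)
    finals = rng.choice(out_keys, size=n, p=out_p)
    extra_out_u = rng.random(n)
    extra_rx_u = rng.random(n)
    extra_rx_idx = rng.integers(0, len(config.other_reactions), size=n)
    # second independent index for non-event reports needing a distinct extra
    extra_rx_idx2 = rng.integers(0, len(config.other_reactions), size=n)
    extra_out_pick = rng.random(n)

    from .clean import SEVERITY_ORDER

    records: list[ReportRecord] = []
    for i in range(n):
        band = bands[i]
        if band == "NA":
            age = None
        else:
            lo, hi = _AGE_BOUNDS[band]
            age = round(float(lo + (hi - lo) * age_u[i]), 1)
        drugs = [
            DrugEntry(verbatim_name=names[j], standardized_name=names[j])
            for j in np.flatnonzero(exposure[i])
        ]
        if event[i]:
            reactions = [config.event_pt]
            if extra_rx_u[i] < config.extra_reaction_rate:
                reactions.append(config.other_reactions[extra_rx_idx[i]])
        else:
            reactions = [config.other_reactions[extra_rx_idx[i]]]
            if extra_rx_u[i] < config.extra_reaction_rate:
                other = config.other_reactions[extra_rx_idx2[i]]
                if other != reactions[0]:
                    reactions.append(other)
        final = str(finals[i])
        if final == "NA":
            outcomes: list[str] = []
        else:
            outcomes = [final]
            lower = SEVERITY_ORDER[SEVERITY_ORDER.index(final) + 1 :]
            if lower and extra_out_u[i] < config.extra_outcome_rate:
                outcomes.append(lower[int(extra_out_pick[i] * len(lower))])
        records.append(
            ReportRecord(
                report_id=f"R{i:07d}",
                case_id=f"C{i:07d}",
                receipt_date=_dt.date(int(years[i]), int(months[i]), int(days[i])),
                age_years=age,
                sex=str(sexes[i]),
                occupation=str(occs[i]),
                country=str(ctys[i]),
                drugs=drugs,
                reactions=reactions,
                outcomes=outcomes,
            )
        )

    n_dup = config.n_duplicates
    if n_dup:
        dup_sources = rng.choice(n, size=n_dup, replace=False)
        for j, src in enumerate(dup_sources):
            dup = records[int(src)].copy()
            dup.report_id = f"R{n + j:07d}"
            records.append(dup)
    return records


def sample_tables(
    config: SyntheticConfig,
    drug: str,
    n_datasets: int,
    seed: int | None = None,
) -> list[FourFoldTable]:
    """Simulate ``n_datasets`` databases and cross-tabulate one drug.

    Uses the same exposure/event core as :func:`generate` without
    materialising records, so calibration and coverage studies over many
    replicates stay cheap.  Duplicates are not injected (calibration targets
    the statistics, not the cleaning).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = list(config.drug_catalog)
    j = names.index(drug)
    tables = []
    for _ in range(n_datasets):
        _, exposure, event = _draw_exposure_events(config, rng, config.n_reports)
        exp_j = exposure[:, j]
        a = int(np.sum(exp_j & event))
        b = int(np.sum(exp_j & ~event))
        c = int(np.sum(~exp_j & event))
        d = int(np.sum(~exp_j & ~event))
        tables.append(FourFoldTable(a, b, c, d))
    return tables
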