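"""Parsing, normalization and the ten-stage prescription cleaning cascade.

Primary-care prescription extracts are noisy: records arrive with brand
names, combination products, missing or impossible dates, and entries issued
after a participant's death.  The cleaning cascade applies, in a fixed
order,

1.  removal of records without any drug content,
2.  removal of records with missing or impossible dates,
3.  separation of combination products into one record per component,
4.  removal of records dated after the participant's death,
5.  aggregation to participant-year pairs,
6.  removal of years after the end of a supplier's prescription coverage,
7.  removal of each participant's first observed year (likely incomplete),
8.  restriction to the sampling window (2000–2015 by default),
9.  removal of participants carrying exclusion diagnoses,
10. removal of records within 365 days before (or any time after) the
    participant's assessment date, to avoid acute drug effects,

and returns the surviving records, the participant-year table and a
complete per-stage audit.  Conservation (``n_in − n_removed = n_out``) is
asserted at every stage; stage 3 may *add* records, in which case
``n_removed`` is negative.

Stage 7 is data-relative: it removes the earliest remaining year per
participant, so re-running the full cascade on its own output removes a
further year at that stage.  All other stages are idempotent filters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ROUTES = ("oral", "ophthalmic", "otic", "nasal", "topical", "parenteral", "unknown")

#: Prescription data are complete until this date; later dates are impossible.
DEFAULT_EXTRACTION_DATE = pd.Timestamp("2016-05-31")

#: Earliest plausible issue date.
EARLIEST_PLAUSIBLE = pd.Timestamp("1900-01-01")

DEFAULT_WINDOW = (2000, 2015)

REQUIRED_COLUMNS = ("participant_id", "date", "drug", "route", "supplier")

STAGE_NAMES = {
    1: "drop records without drug content",
    2: "drop records with missing or impossible dates",
    3: "split combination products",
    4: "drop records after participant death",
    5: "aggregate to participant-years",
    6: "drop years after supplier coverage end",
    7: "drop each participant's first observed year",
    8: "restrict to sampling window",
    9: "drop participants with exclusion diagnoses",
    10: "drop records within a year before assessment or after it",
}


class FormatError(ValueError):
    """Raised when an input file does not match the documented dialect."""


class ConfigurationError(ValueError):
    """Raised for inconsistent cleaning configuration."""


@dataclass
class StageAudit:
    stage: int
    name: str
    unit: str  # "records" or "participant-years"
    n_in: int
    n_removed: int
    n_out: int

    def __post_init__(self) -> None:
        if self.n_out != self.n_in - self.n_removed:
            raise AssertionError(
                f"stage {self.stage}: conservation violated ({self.n_in} - {self.n_removed} != {self.n_out})"
            )


@dataclass
class CleaningAudit:
    """Per-stage record/row counts for one cascade run."""

    stages: list[StageAudit] = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    def add(self, stage: int, unit: str, n_in: int, n_out: int) -> None:
        self.stages.append(StageAudit(stage, STAGE_NAMES[stage], unit, n_in, n_in - n_out, n_out))

    def removed(self, stage: int) -> int:
        for s in self.stages:
            if s.stage == stage:
                return s.n_removed
        raise KeyError(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.stages])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"stages": [vars(s) for s in self.stages], "notes": self.notes}, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def validate_chain(self) -> None:
        """Stages sharing a unit must chain exactly (out of one = in of next)."""
        for prev, cur in zip(self.stages, self.stages[1:]):
            if prev.unit == cur.unit and cur.n_in != prev.n_out:
                raise AssertionError(f"audit chain broken between stages {prev.stage} and {cur.stage}")


@dataclass
class CleanResult:
    """Output of :func:`clean_cascade`.

    ``records`` are the fully cleaned prescription records (with a ``year``
    column); ``participant_years`` the aggregated (participant, year) table;
    ``records_pre_assessment_filter`` the records surviving stages 1–9,
    retained so sensitivity analyses can invert stage 10.
    """

    records: pd.DataFrame
    participant_years: pd.DataFrame
    audit: CleaningAudit
    records_pre_assessment_filter: pd.DataFrame | None = None


def read_prescriptions(path: str | Path) -> pd.DataFrame:
    """Read a prescriptions CSV into a tidy record table.

    Unparseable or missing dates are retained as NaT so the cascade's
    stage 2 removes and counts them rather than the reader silently
    dropping rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"prescriptions file {path}: missing required column(s) {missing}")
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "issue_date": pd.to_datetime(df["date"], errors="coerce", format="%Y-%m-%d"),
            "drug_raw": df["drug"].str.strip(),
            "route": df["route"].where(df["route"].isin(ROUTES), "unknown"),
            "supplier": df["supplier"],
        }
    )
    return out


_DOSE_TOKEN = r"^\d+(\.\d+)?\s*(mg|mcg|microgram(s)?|g|ml|iu|%)?$"
_UNIT_TOKENS = {"mg", "mcg", "microgram", "micrograms", "g", "ml", "iu", "%", "tablet", "tablets", "capsule", "capsules"}


def _canonical(name: str) -> str:
    """Lower-case, strip, drop trailing dose-like tokens ('50mg', '25 mg', '5 ml')."""
    tokens = str(name).strip().lower().split()
    import re

    while tokens and (re.match(_DOSE_TOKEN, tokens[-1]) or tokens[-1] in _UNIT_TOKENS):
        tokens.pop()
    return " ".join(tokens)


def normalize_names(
    records: pd.DataFrame,
    brand_map: dict[str, str],
    formulary: set[str],
) -> pd.DataFrame:
    """Resolve raw drug strings to generic names.

    Matching is case-insensitive, ignores surrounding whitespace, and drops
    trailing dose tokens.  Brand names map through *brand_map*; strings
    already in *formulary* pass through; anything else gets an empty
    ``drug_generic`` and is removed (and audited) at cascade stage 1.
    """
    bad = sorted(set(brand_map.values()) - set(formulary))
    if bad:
        raise ConfigurationError(f"brand_map targets outside the formulary: {bad}")
    lookup = {_canonical(k): v for k, v in brand_map.items()}
    formulary_canon = {_canonical(g): g for g in formulary}

    def resolve(raw: str) -> str:
        c = _canonical(raw)
        if c in lookup:
            return lookup[c]
        return formulary_canon.get(c, "")

    out = records.copy()
    uniq = out["drug_raw"].astype(str).unique()
    mapping = {u: resolve(u) for u in uniq}
    out["drug_generic"] = out["drug_raw"].astype(str).map(mapping)
    return out


def split_combinations(
    records: pd.DataFrame,
    combos: dict[str, list[str]],
    formulary: set[str] | None = None,
) -> pd.DataFrame:
    """Replace each combination-product record by one record per component.

    All other fields are copied; output order is stable (input order, then
    component order).
    """
    for product, comps in combos.items():
        if len(comps) < 2:
            raise ConfigurationError(f"combination {product!r} has fewer than 2 components")
        if formulary is not None:
            missing = [c for c in comps if c not in formulary]
            if missing:
                raise ConfigurationError(f"combination {product!r} components missing from formulary: {missing}")
    if records.empty or not combos:
        return records.copy()
    is_combo = records["drug_generic"].isin(combos)
    if not is_combo.any():
        return records.copy()
    parts: list[pd.DataFrame] = []
    plain = records[~is_combo]
    combo_rows = records[is_combo]
    n_components = combo_rows["drug_generic"].map(lambda p: len(combos[p]))
    expanded = combo_rows.loc[combo_rows.index.repeat(n_components)].copy()
    expanded["drug_generic"] = np.concatenate([combos[p] for p in combo_rows["drug_generic"]])
    out = pd.concat([plain, expanded]).sort_index(kind="stable").reset_index(drop=True)
    return out


def _participant_lookup(participants: pd.DataFrame, column: str) -> pd.Series:
    if column in participants.columns:
        return participants.set_index("participant_id")[column]
    return pd.Series(dtype="object")


def clean_cascade(
    records: pd.DataFrame,
    participants: pd.DataFrame,
    window: tuple[int, int] = DEFAULT_WINDOW,
    combos: dict[str, list[str]] | None = None,
    extraction_date: pd.Timestamp = DEFAULT_EXTRACTION_DATE,
    coverage_end: dict[str, int] | None = None,
    assessment_rule: str = "days365",
    drop_first_year: bool = True,
) -> CleanResult:
    """Run the ten-stage cleaning cascade.

    Parameters
    ----------
    records
        Normalized record table (``drug_generic`` column present; use
        :func:`normalize_names` first, or raw generics are assumed).
    participants
        One row per participant: ``participant_id``, ``assessment_date``,
        optional ``death_date``, ``birth_year``, ``has_exclusion_dx``.
    window
        Inclusive (start_year, end_year) sampling window for stage 8.
    combos
        Combination-product map for stage 3 (empty → stage is a no-op).
    extraction_date
        Last date with complete prescription coverage; later issue dates are
        impossible (stage 2).
    coverage_end
        Supplier → last complete year (stage 6).  Defaults to the window end
        for every supplier.
    assessment_rule
        ``"days365"`` (default): stage 10 drops records dated on or after
        ``assessment_date − 365 days``.  ``"calendar"``: drops whole
        participant-years with year ≥ assessment year.
    drop_first_year
        Apply stage 7 (the first observed year per participant is unlikely
        to be complete).  Disabling it makes the cascade idempotent.
    """
    if assessment_rule not in ("days365", "calendar"):
        raise ConfigurationError(f"unknown assessment_rule {assessment_rule!r}")
    audit = CleaningAudit()
    rec = records.copy()
    if "drug_generic" not in rec.columns:
        rec["drug_generic"] = rec["drug_raw"]

    # stage 1: records without drug content
    n_in = len(rec)
    rec = rec[rec["drug_generic"].astype(str).str.len() > 0]
    audit.add(1, "records", n_in, len(rec))

    # stage 2: missing or impossible dates
    n_in = len(rec)
    dates = pd.to_datetime(rec["issue_date"])
    ok = dates.notna() & (dates >= EARLIEST_PLAUSIBLE) & (dates <= extraction_date)
    birth = _participant_lookup(participants, "birth_year")
    if not birth.empty:
        birth_years = rec["participant_id"].map(birth)
        ok &= ~(dates.dt.year < birth_years.fillna(-np.inf))
    rec = rec[ok]
    audit.add(2, "records", n_in, len(rec))

    # stage 3: split combination products (may add records; n_removed < 0)
    n_in = len(rec)
    rec = split_combinations(rec, combos or {})
    audit.add(3, "records", n_in, len(rec))

    # stage 4: records after participant death
    n_in = len(rec)
    death = _participant_lookup(participants, "death_date")
    if not death.empty:
        death_dates = pd.to_datetime(rec["participant_id"].map(death))
        rec = rec[~(pd.to_datetime(rec["issue_date"]) > death_dates)]
    audit.add(4, "records", n_in, len(rec))

    # stage 5: aggregate to participant-years (transformation, not removal)
    rec = rec.copy()
    rec["year"] = pd.to_datetime(rec["issue_date"]).dt.year.astype(int)
    n_in = len(rec)
    py = rec.groupby(["participant_id", "year"]).size().rename("n_prescriptions").reset_index()
    audit.add(5, "records->participant-years", n_in, len(py))

    def _filter_years(keep: pd.Series, stage: int) -> None:
        nonlocal rec, py
        n = len(py)
        py_local = py[keep.to_numpy()]
        kept = set(map(tuple, py_local[["participant_id", "year"]].itertuples(index=False)))
        rec = rec[[t in kept for t in zip(rec["participant_id"], rec["year"])]]
        py = py_local
        audit.add(stage, "participant-years", n, len(py))

    # stage 6: years after supplier coverage end
    cov = coverage_end or {}
    default_cov = window[1]
    rec_cov = rec["supplier"].map(lambda s: cov.get(s, default_cov))
    keep_rec = rec["year"] <= rec_cov
    n = len(py)
    rec = rec[keep_rec]
    py = rec.groupby(["participant_id", "year"]).size().rename("n_prescriptions").reset_index()
    audit.add(6, "participant-years", n, len(py))

    # stage 7: first observed year per participant
    if drop_first_year:
        first = py.groupby("participant_id")["year"].transform("min")
        _filter_years(py["year"] > first, 7)
    else:
        audit.add(7, "participant-years", len(py), len(py))

    # stage 8: sampling window
    _filter_years((py["year"] >= window[0]) & (py["year"] <= window[1]), 8)

    # stage 9: participants with exclusion diagnoses
    excl = _participant_lookup(participants, "has_exclusion_dx")
    if not excl.empty:
        flag = py["participant_id"].map(excl).fillna(False).astype(bool)
        audit.notes["participants_excluded_stage9"] = int(py.loc[flag, "participant_id"].nunique())
        _filter_years(~flag, 9)
    else:
        audit.add(9, "participant-years", len(py), len(py))

    records_pre10 = rec.copy()

    # stage 10: assessment-proximity exclusion
    assess = pd.to_datetime(_participant_lookup(participants, "assessment_date"))
    n = len(py)
    assess_dates = pd.to_datetime(rec["participant_id"].map(assess))
    missing_assess = assess_dates.isna()
    audit.notes["participants_missing_assessment"] = int(rec.loc[missing_assess, "participant_id"].nunique())
    if assessment_rule == "days365":
        cutoff = assess_dates - pd.Timedelta(days=365)
        keep = (~missing_assess) & (pd.to_datetime(rec["issue_date"]) < cutoff)
    else:
        keep = (~missing_assess) & (rec["year"] < assess_dates.dt.year)
    rec = rec[keep]
    py = rec.groupby(["participant_id", "year"]).size().rename("n_prescriptions").reset_index()
    audit.add(10, "participant-years", n, len(py))

    audit.validate_chain()
    return CleanResult(
        records=rec.reset_index(drop=True),
        participant_years=py,
        audit=audit,
        records_pre_assessment_filter=records_pre10.reset_index(drop=True),
    )
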