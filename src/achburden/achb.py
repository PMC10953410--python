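"""Anticholinergic burden scoring and aggregation.

An anticholinergic scale is a published list assigning an ordinal potency
(typically 1–3, with 0.5 for drugs of improbable anticholinergic action) to
generic drug names.  A participant's cumulative anticholinergic burden (AChB)
over a sampling window is the sum of per-prescription potencies.  Scales are
partial lists by construction, so drugs absent from a scale score 0 rather
than raising an error.

Two scoring rules apply on top of the potency lookup:

* prescriptions with ophthalmic, otic, nasal or topical routes of
  administration score 0 (negligible systemic absorption);
* drugs flagged as having *improbable anticholinergic action* score 0.5 on
  scales modified to carry that rule (see :func:`apply_improbable_rule`).

All aggregation functions operate on tidy prescription-record DataFrames as
produced by :func:`achburden.prescriptions.clean_cascade` (columns
``participant_id``, ``year``, ``drug_generic``, ``route``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

#: Routes of administration with negligible systemic anticholinergic exposure.
NON_SYSTEMIC_ROUTES = frozenset({"ophthalmic", "otic", "nasal", "topical"})

#: Potency assigned to drugs with improbable anticholinergic action.
IMPROBABLE_POTENCY = 0.5

VALID_POTENCIES = frozenset({0.5, 1.0, 2.0, 3.0})


class ScaleError(ValueError):
    """Raised for malformed anticholinergic scale definitions."""


class AtcError(ValueError):
    """Raised when a scored drug has no ATC assignment."""


@dataclass(frozen=True)
class AnticholinergicScale:
    """A named drug → potency map.

    Parameters
    ----------
    name
        Scale identifier.
    potencies
        Mapping from generic drug name to potency in {0.5, 1, 2, 3}.
        Drugs not listed implicitly score 0.
    improbable_set
        Generics flagged as having improbable anticholinergic action.  On a
        *modified* scale these score :data:`IMPROBABLE_POTENCY` after
        :func:`apply_improbable_rule`.
    modified
        Whether the scale carries post-publication modifications (newer
        drugs added, or the improbable-action rule).
    """

    name: str
    potencies: dict[str, float]
    improbable_set: frozenset[str] = field(default_factory=frozenset)
    modified: bool = False

    def __post_init__(self) -> None:
        bad = {d: v for d, v in self.potencies.items() if v not in VALID_POTENCIES}
        if bad:
            raise ScaleError(f"scale {self.name!r}: potencies outside {{0.5,1,2,3}}: {bad}")
        stray = set(self.improbable_set) - set(self.potencies)
        if stray:
            raise ScaleError(f"scale {self.name!r}: improbable drugs not in potency map: {sorted(stray)}")

    @property
    def n_drugs(self) -> int:
        return len(self.potencies)

    def potency_of(self, generic: str) -> float:
        return self.potencies.get(generic, 0.0)


def apply_improbable_rule(scale: AnticholinergicScale) -> AnticholinergicScale:
    """Return a copy of *scale* with improbable-action drugs scored 0.5."""
    if not scale.improbable_set:
        return scale
    pot = dict(scale.potencies)
    for drug in scale.improbable_set:
        pot[drug] = IMPROBABLE_POTENCY
    return replace(scale, potencies=pot, modified=True)


def score_record(drug_generic: str, route: str, scale: AnticholinergicScale) -> float:
    """Potency of one prescription under *scale*.

    Non-systemic routes score 0 regardless of the drug; unlisted drugs
    score 0.
    """
    if route in NON_SYSTEMIC_ROUTES:
        return 0.0
    return scale.potency_of(drug_generic)


def score_records(records: pd.DataFrame, scale: AnticholinergicScale) -> pd.Series:
    """Vectorized :func:`score_record` over a record table."""
    pot = records["drug_generic"].map(scale.potencies).fillna(0.0)
    pot = pot.where(~records["route"].isin(NON_SYSTEMIC_ROUTES), 0.0)
    return pot.astype(float)


def _ensure_year(records: pd.DataFrame) -> pd.DataFrame:
    if "year" in records.columns:
        return records
    out = records.copy()
    out["year"] = pd.to_datetime(out["issue_date"]).dt.year
    return out


def yearly_burden(records: pd.DataFrame, scale: AnticholinergicScale) -> pd.DataFrame:
    """Per participant-year AChB, anticholinergic count and prescription count."""
    rec = _ensure_year(records)
    pot = score_records(rec, scale)
    g = pd.DataFrame(
        {
            "participant_id": rec["participant_id"].to_numpy(),
            "year": rec["year"].to_numpy(),
            "achb": pot.to_numpy(),
            "ac_count": (pot.to_numpy() > 0).astype(int),
            "n_prescriptions": 1,
        }
    ).groupby(["participant_id", "year"], as_index=False, sort=True).sum()
    return g


def cumulative_burden(
    records: pd.DataFrame,
    scale: AnticholinergicScale,
    window: tuple[int, int] | None = None,
    participants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cumulative AChB per participant over *window* (inclusive years).

    Returns one row per participant with ``achb`` (sum of potencies),
    ``ac_count`` (number of anticholinergic prescriptions), ``n_prescriptions``
    and ``n_years`` (distinct years with at least one prescription in the
    window).  Participants listed in *participants* but absent from the
    records get AChB 0 with ``n_years`` 0.
    """
    yearly = yearly_burden(records, scale)
    if window is not None:
        lo, hi = window
        yearly = yearly[(yearly["year"] >= lo) & (yearly["year"] <= hi)]
        if yearly.empty and not records.empty:
            import warnings

            warnings.warn(f"window {window} contains no cleaned prescription-years", stacklevel=2)
    out = (
        yearly.groupby("participant_id", as_index=False)
        .agg(achb=("achb", "sum"), ac_count=("ac_count", "sum"), n_prescriptions=("n_prescriptions", "sum"), n_years=("year", "nunique"))
    )
    if participants is not None:
        ids = participants["participant_id"] if "participant_id" in participants else pd.Series(participants)
        out = (
            pd.DataFrame({"participant_id": pd.unique(ids)})
            .merge(out, on="participant_id", how="left")
            .fillna({"achb": 0.0, "ac_count": 0, "n_prescriptions": 0, "n_years": 0})
        )
        out[["ac_count", "n_prescriptions", "n_years"]] = out[["ac_count", "n_prescriptions", "n_years"]].astype(int)
    return out


def atc_class(code: str, level: int) -> str:
    """ATC class key: first letter (level 1) or first four characters (level 3)."""
    if level == 1:
        return code[:1]
    if level == 3:
        return code[:4]
    raise ValueError(f"supported ATC levels are 1 and 3, got {level}")


def _atc_series(atc_map: pd.DataFrame) -> pd.Series:
    return atc_map.set_index("generic")["atc_code"]


def burden_by_class(
    records: pd.DataFrame,
    scale: AnticholinergicScale,
    atc_map: pd.DataFrame,
    level: int = 3,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """AChB decomposed by ATC class: one row per (participant, class).

    Every drug that scores under *scale* must carry exactly one ATC code in
    *atc_map* (columns ``generic``, ``atc_code``); the per-class sums then
    reconcile exactly with :func:`cumulative_burden`.
    """
    rec = _ensure_year(records)
    if window is not None:
        rec = rec[(rec["year"] >= window[0]) & (rec["year"] <= window[1])]
    pot = score_records(rec, scale)
    scored = rec.loc[pot.to_numpy() > 0, ["participant_id", "drug_generic"]].copy()
    scored["achb"] = pot.to_numpy()[pot.to_numpy() > 0]
    codes = _atc_series(atc_map)
    missing = sorted(set(scored["drug_generic"]) - set(codes.index))
    if missing:
        raise AtcError(f"scored drugs missing from the ATC map: {missing}")
    scored["atc_class"] = scored["drug_generic"].map(codes).str.slice(0, 1 if level == 1 else 4)
    if level not in (1, 3):
        raise ValueError(f"supported ATC levels are 1 and 3, got {level}")
    return scored.groupby(["participant_id", "atc_class"], as_index=False)["achb"].sum()


def class_eligibility(
    records: pd.DataFrame,
    atc_map: pd.DataFrame,
    level: int = 3,
    min_participants: int = 100,
) -> set[str]:
    """ATC classes prescribed to at least *min_participants* distinct participants.

    Classes below the threshold are excluded from class-specific association
    models; the count is over participants with at least one prescription of
    any drug in the class.
    """
    codes = _atc_series(atc_map)
    rec = records[["participant_id", "drug_generic"]].copy()
    rec["atc_class"] = rec["drug_generic"].map(codes).str.slice(0, 1 if level == 1 else 4)
    rec = rec.dropna(subset=["atc_class"])
    counts = rec.groupby("atc_class")["participant_id"].nunique()
    return set(counts.index[counts >= min_participants])


def polypharmacy_counts(
    records: pd.DataFrame,
    scale: AnticholinergicScale,
    distinct_drugs: bool = False,
) -> pd.DataFrame:
    """Total and non-anticholinergic prescription counts per participant.

    The non-anticholinergic count is the total minus prescriptions scoring
    > 0 under *scale*, so it differs across scales.  With
    ``distinct_drugs=True`` counts are over distinct generic names instead of
    prescriptions.
    """
    pot = score_records(records, scale)
    df = pd.DataFrame(
        {
            "participant_id": records["participant_id"].to_numpy(),
            "drug_generic": records["drug_generic"].to_numpy(),
            "is_ac": pot.to_numpy() > 0,
        }
    )
    if distinct_drugs:
        df = df.drop_duplicates(subset=["participant_id", "drug_generic"])
    out = df.groupby("participant_id", as_index=False).agg(total=("is_ac", "size"), n_anticholinergic=("is_ac", "sum"))
    out["n_non_anticholinergic"] = out["total"] - out["n_anticholinergic"]
    return out


def build_burden_table(
    records: pd.DataFrame,
    scales: list[AnticholinergicScale],
    atc_map: pd.DataFrame | None = None,
    window: tuple[int, int] | None = None,
    participants: pd.DataFrame | None = None,
    class_levels: tuple[int, ...] = (),
) -> pd.DataFrame:
    """Wide per-participant burden table across scales (and optionally classes).

    Columns: ``achb_<scale>``, ``count_<scale>`` (anticholinergic
    prescriptions), ``nonac_<scale>``, shared ``total_rx`` and ``n_years``,
    and with *class_levels* also ``achb_<scale>_L<level>_<class>``.
    """
    rec = _ensure_year(records)
    if window is not None:
        rec = rec[(rec["year"] >= window[0]) & (rec["year"] <= window[1])]
    base_ids = participants if participants is not None else pd.DataFrame({"participant_id": pd.unique(rec["participant_id"])})
    out = pd.DataFrame({"participant_id": pd.unique(base_ids["participant_id"])}).sort_values("participant_id").reset_index(drop=True)
    totals = rec.groupby("participant_id").size().rename("total_rx")
    years = rec.groupby("participant_id")["year"].nunique().rename("n_years")
    out = out.merge(totals, on="participant_id", how="left").merge(years, on="participant_id", how="left")
    out[["total_rx", "n_years"]] = out[["total_rx", "n_years"]].fillna(0).astype(int)
    for scale in scales:
        cb = cumulative_burden(rec, scale, window=None, participants=out)
        out[f"achb_{scale.name}"] = cb["achb"].to_numpy()
        out[f"count_{scale.name}"] = cb["ac_count"].to_numpy()
        out[f"nonac_{scale.name}"] = out["total_rx"] - out[f"count_{scale.name}"]
        for level in class_levels:
            if atc_map is None:
                raise AtcError("class_levels requested but no ATC map supplied")
            bc = burden_by_class(rec, scale, atc_map, level=level)
            wide = bc.pivot(index="participant_id", columns="atc_class", values="achb")
            wide.columns = [f"achb_{scale.name}_L{level}_{c}" for c in wide.columns]
            out = out.merge(wide, on="participant_id", how="left")
            out[wide.columns] = out[wide.columns].fillna(0.0)
    return out
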