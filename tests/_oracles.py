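"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain per-record Python loops, deliberately
sharing no code with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NON_SYSTEMIC = {"ophthalmic", "otic", "nasal", "topical"}


def record_potency(drug: str, route: str, potencies: dict) -> float:
    if route in NON_SYSTEMIC:
        return 0.0
    return potencies.get(drug, 0.0)


def brute_cumulative(records: pd.DataFrame, scale, window=None) -> dict:
    """Per-participant {achb, ac_count, total, years} by record-by-record summation."""
    out: dict = {}
    for row in records.itertuples(index=False):
        year = int(row.year)
        if window is not None and not (window[0] <= year <= window[1]):
            continue
        p = record_potency(row.drug_generic, row.route, scale.potencies)
        d = out.setdefault(row.participant_id, {"achb": 0.0, "ac_count": 0, "total": 0, "years": set()})
        d["achb"] += p
        d["ac_count"] += int(p > 0)
        d["total"] += 1
        d["years"].add(year)
    return out


def brute_by_class(records: pd.DataFrame, scale, atc_map: pd.DataFrame, level: int, window=None) -> dict:
    codes = dict(zip(atc_map["generic"], atc_map["atc_code"]))
    width = 1 if level == 1 else 4
    out: dict = {}
    for row in records.itertuples(index=False):
        year = int(row.year)
        if window is not None and not (window[0] <= year <= window[1]):
            continue
        p = record_potency(row.drug_generic, row.route, scale.potencies)
        if p > 0:
            key = (row.participant_id, codes[row.drug_generic][:width])
            out[key] = out.get(key, 0.0) + p
    return out


def brute_polypharmacy(records: pd.DataFrame, scale) -> dict:
    out: dict = {}
    for row in records.itertuples(index=False):
        p = record_potency(row.drug_generic, row.route, scale.potencies)
        d = out.setdefault(row.participant_id, {"total": 0, "ac": 0})
        d["total"] += 1
        d["ac"] += int(p > 0)
    for d in out.values():
        d["non_ac"] = d["total"] - d["ac"]
    return out


def brute_bh(pvals, alpha: float = 0.05):
    """Benjamini–Hochberg step-up: (reject flags, adjusted p) by definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    if k_star:
        reject[order[:k_star]] = True
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj[order[rank - 1]] = running
    return reject, adj


def brute_cascade_expectations(
    records: pd.DataFrame,
    participants: pd.DataFrame,
    combos: dict,
    window=(2000, 2015),
    extraction=pd.Timestamp("2016-05-31"),
) -> list[dict]:
    """Expected per-stage counts of the cleaning cascade, by explicit loops.

    Records must already carry ``drug_generic``.  Returns one dict per stage
    with n_in / n_removed / n_out in the cascade's units.
    """
    info = participants.set_index("participant_id")
    rows = [
        {
            "pid": r.participant_id,
            "date": r.issue_date,
            "drug": r.drug_generic,
            "route": r.route,
            "supplier": r.supplier,
        }
        for r in records.itertuples(index=False)
    ]
    stages = []

    def log(stage, unit, n_in, n_out):
        stages.append({"stage": stage, "unit": unit, "n_in": n_in, "n_removed": n_in - n_out, "n_out": n_out})

    n = len(rows)
    rows = [r for r in rows if isinstance(r["drug"], str) and r["drug"] != ""]
    log(1, "records", n, len(rows))

    def date_ok(r):
        d = r["date"]
        if pd.isna(d):
            return False
        if d < pd.Timestamp("1900-01-01") or d > extraction:
            return False
        by = info.loc[r["pid"], "birth_year"] if "birth_year" in info.columns else None
        if by is not None and not pd.isna(by) and d.year < by:
            return False
        return True

    n = len(rows)
    rows = [r for r in rows if date_ok(r)]
    log(2, "records", n, len(rows))

    n = len(rows)
    expanded = []
    for r in rows:
        if r["drug"] in combos:
            for comp in combos[r["drug"]]:
                expanded.append({**r, "drug": comp})
        else:
            expanded.append(r)
    rows = expanded
    log(3, "records", n, len(rows))

    def alive(r):
        dd = info.loc[r["pid"], "death_date"] if "death_date" in info.columns else pd.NaT
        return pd.isna(dd) or r["date"] <= dd

    n = len(rows)
    rows = [r for r in rows if alive(r)]
    log(4, "records", n, len(rows))

    def year_pairs(rs):
        return {(r["pid"], r["date"].year) for r in rs}

    log(5, "records->participant-years", len(rows), len(year_pairs(rows)))

    n = len(year_pairs(rows))
    rows = [r for r in rows if r["date"].year <= window[1]]  # default coverage end
    log(6, "participant-years", n, len(year_pairs(rows)))

    firsts = {}
    for r in rows:
        y = r["date"].year
        firsts[r["pid"]] = min(firsts.get(r["pid"], 9999), y)
    n = len(year_pairs(rows))
    rows = [r for r in rows if r["date"].year > firsts[r["pid"]]]
    log(7, "participant-years", n, len(year_pairs(rows)))

    n = len(year_pairs(rows))
    rows = [r for r in rows if window[0] <= r["date"].year <= window[1]]
    log(8, "participant-years", n, len(year_pairs(rows)))

    n = len(year_pairs(rows))
    rows = [r for r in rows if not bool(info.loc[r["pid"], "has_exclusion_dx"])]
    log(9, "participant-years", n, len(year_pairs(rows)))

    def pre_assessment(r):
        ad = info.loc[r["pid"], "assessment_date"]
        if pd.isna(ad):
            return False
        return r["date"] < ad - pd.Timedelta(days=365)

    n = len(year_pairs(rows))
    rows = [r for r in rows if pre_assessment(r)]
    log(10, "participant-years", n, len(year_pairs(rows)))
    return stages
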