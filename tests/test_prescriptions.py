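"""Parsing, normalization and the ten-stage cleaning cascade."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_cascade_expectations
from achburden import prescriptions as rx


def _write(tmp_path, text, name="rx.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPrescriptions:
    def test_reads_valid_rows(self, tmp_path):
        p = _write(
            tmp_path,
            "participant_id,date,drug,route,supplier\n"
            "p1,2005-03-01,sertraline,oral,scotland\n"
            "p2,2006-04-02,amitriptyline,topical,wales\n"
            "p3,2007-05-03,Zoloft 50mg,oral,wales\n",
        )
        rec = rx.read_prescriptions(p)
        assert len(rec) == 3
        assert rec.loc[0, "issue_date"] == pd.Timestamp("2005-03-01")
        assert rec.loc[1, "route"] == "topical"

    def test_unparseable_dates_kept_as_null(self, tmp_path):
        p = _write(
            tmp_path,
            "participant_id,date,drug,route,supplier\np1,3015-01-01,a,oral,s\np2,,b,oral,s\np3,garbage,c,oral,s\n",
        )
        rec = rx.read_prescriptions(p)
        assert len(rec) == 3
        assert rec["issue_date"].isna().all()  # retained for stage-2 audit, not dropped

    def test_empty_file_with_header(self, tmp_path):
        p = _write(tmp_path, "participant_id,date,drug,route,supplier\n")
        assert rx.read_prescriptions(p).empty

    def test_missing_column_named_in_error(self, tmp_path):
        p = _write(tmp_path, "participant_id,date,route,supplier\np1,2005-01-01,oral,s\n")
        with pytest.raises(rx.FormatError, match="drug"):
            rx.read_prescriptions(p)


class TestNormalizeNames:
    BRAND_MAP = {"Zoloft": "sertraline", "Elavil": "amitriptyline"}
    FORMULARY = {"sertraline", "amitriptyline", "loratadine"}

    def _records(self, raws):
        return pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(len(raws))],
                "issue_date": pd.Timestamp("2005-01-01"),
                "drug_raw": raws,
                "route": "oral",
                "supplier": "s",
            }
        )

    @pytest.mark.parametrize(
        ("raw", "expected"),
        [
            ("Zoloft 50mg", "sertraline"),
            ("zoloft", "sertraline"),
            ("  ELAVIL 25 mg ", "amitriptyline"),
            ("sertraline", "sertraline"),
            ("Loratadine 10mg", "loratadine"),
            ("xyzzy", ""),
        ],
    )
    def test_resolution(self, raw, expected):
        out = rx.normalize_names(self._records([raw]), self.BRAND_MAP, self.FORMULARY)
        assert out.loc[0, "drug_generic"] == expected

    def test_brand_map_outside_formulary_rejected(self):
        with pytest.raises(rx.ConfigurationError):
            rx.normalize_names(self._records(["a"]), {"X": "not-a-generic"}, self.FORMULARY)


class TestSplitCombinations:
    def _records(self, drugs):
        return pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(len(drugs))],
                "issue_date": pd.Timestamp("2005-01-01"),
                "drug_generic": drugs,
                "route": "oral",
                "supplier": "s",
            }
        )

    def test_two_component_product_yields_two_records(self):
        out = rx.split_combinations(self._records(["co-thing"]), {"co-thing": ["a", "b"]})
        assert list(out["drug_generic"]) == ["a", "b"]
        assert out["issue_date"].nunique() == 1
        assert (out["route"] == "oral").all()

    def test_no_combination_records_identity(self):
        rec = self._records(["a", "b"])
        out = rx.split_combinations(rec, {"co": ["a", "b"]})
        pd.testing.assert_frame_equal(out, rec)

    def test_multiplicative_expansion(self):
        rec = self._records(["tri", "tri", "tri"])
        out = rx.split_combinations(rec, {"tri": ["a", "b", "c"]})
        assert len(out) == 9
        # stable ordering: input order then component order
        assert list(out["drug_generic"]) == ["a", "b", "c"] * 3

    def test_component_missing_from_formulary(self):
        with pytest.raises(rx.ConfigurationError, match="missing"):
            rx.split_combinations(self._records(["co"]), {"co": ["a", "zzz"]}, formulary={"a", "co"})

    def test_single_component_combo_rejected(self):
        with pytest.raises(rx.ConfigurationError):
            rx.split_combinations(self._records(["co"]), {"co": ["a"]})


def _mini_participants():
    return pd.DataFrame(
        {
            "participant_id": ["p1", "p2", "p3"],
            "assessment_date": pd.to_datetime(["2009-06-01", "2010-06-01", "2009-06-01"]),
            "death_date": pd.to_datetime([pd.NaT, "2007-06-30", pd.NaT]),
            "has_exclusion_dx": [False, False, True],
            "birth_year": [1950, 1950, 1950],
        }
    )


def _mini_records():
    """Clean core: p1 prescribed yearly 2001-2009, p2 2001-2006, p3 2003-2004."""
    rows = []
    for pid, years in [("p1", range(2001, 2010)), ("p2", range(2001, 2007)), ("p3", (2003, 2004))]:
        for y in years:
            rows.append((pid, f"{y}-03-15", "druga", "oral", "s"))
    df = pd.DataFrame(rows, columns=["participant_id", "issue_date", "drug_generic", "route", "supplier"])
    df["issue_date"] = pd.to_datetime(df["issue_date"])
    return df


class TestCleanCascade:
    def test_planted_violations_removed_at_the_right_stage(self):
        """Each planted violation class is removed exactly once, at its stage."""
        clean = _mini_records()
        planted = pd.DataFrame(
            {
                "participant_id": ["p1", "p1", "p1", "p1", "p1", "p2", "p1"],
                "issue_date": pd.to_datetime(
                    ["2003-01-01", "2003-01-02", "2003-01-03", pd.NaT, "2200-01-01", "2008-01-01", "1999-05-05"]
                ),
                "drug_generic": ["", "", "", "druga", "druga", "druga", "druga"],
                "route": "oral",
                "supplier": "s",
            }
        )
        rec = pd.concat([clean, planted], ignore_index=True)
        result = rx.clean_cascade(rec, _mini_participants(), drop_first_year=False)
        audit = result.audit
        assert audit.removed(1) == 3  # empty drug strings
        assert audit.removed(2) == 2  # missing + impossible date
        assert audit.removed(4) == 1  # p2 prescribed after 2007 death
        assert audit.removed(8) == 1  # 1999 record outside the 2000-2015 window
        audit.validate_chain()

    def test_first_year_and_exclusion_and_assessment_rules(self):
        result = rx.clean_cascade(_mini_records(), _mini_participants())
        audit = result.audit
        # p3 carries an exclusion diagnosis: both surviving years dropped at stage 9
        assert audit.notes["participants_excluded_stage9"] == 1
        # stage 7 removes one first-year row per participant still present
        assert audit.removed(7) == 3
        # p1 assessed 2009-06-01: records >= 2008-06-01 dropped at stage 10
        kept_p1 = result.records[result.records["participant_id"] == "p1"]
        assert kept_p1["year"].max() <= 2008
        assert (pd.to_datetime(kept_p1["issue_date"]) < pd.Timestamp("2008-06-01")).all()

    def test_calendar_mode_drops_assessment_year(self):
        result = rx.clean_cascade(_mini_records(), _mini_participants(), assessment_rule="calendar")
        kept_p1 = result.records[result.records["participant_id"] == "p1"]
        assert kept_p1["year"].max() == 2008  # < assessment year 2009

    def test_post_death_combination_counts_per_component(self):
        """Stage 3 precedes stage 4, so one post-death combination record of
        two components contributes two stage-4 removals."""
        clean = _mini_records()
        combo = pd.DataFrame(
            {
                "participant_id": ["p2"],
                "issue_date": [pd.Timestamp("2008-02-01")],  # after p2's 2007 death
                "drug_generic": ["co-pill"],
                "route": "oral",
                "supplier": "s",
            }
        )
        rec = pd.concat([clean, combo], ignore_index=True)
        result = rx.clean_cascade(rec, _mini_participants(), combos={"co-pill": ["a", "b"]})
        assert result.audit.removed(3) == -1  # one record became two
        assert result.audit.removed(4) == 2

    def test_all_clean_input_removes_nothing_before_year_stages(self):
        result = rx.clean_cascade(_mini_records(), _mini_participants(), drop_first_year=False)
        for stage in (1, 2, 3, 4, 6, 7):
            assert result.audit.removed(stage) == 0

    def test_cascade_idempotent_without_first_year_stage(self):
        first = rx.clean_cascade(_mini_records(), _mini_participants())
        again = rx.clean_cascade(first.records, _mini_participants(), drop_first_year=False)
        for stage in (1, 2, 3, 4, 6, 7, 8, 9, 10):
            assert again.audit.removed(stage) == 0
        assert len(again.records) == len(first.records)

    def test_missing_assessment_counted_not_raised(self):
        parts = _mini_participants()
        parts.loc[0, "assessment_date"] = pd.NaT
        result = rx.clean_cascade(_mini_records(), parts)
        assert result.audit.notes["participants_missing_assessment"] == 1
        assert "p1" not in set(result.records["participant_id"])

    def test_audit_conservation_enforced(self):
        with pytest.raises(AssertionError):
            rx.StageAudit(1, "x", "records", 10, 3, 8)


def test_cascade_matches_independent_stagewise_oracle(sim_bundle, participants, catalogue):
    """All ten stage counts on a generated stream match a loop-based oracle."""
    normalized = sim_bundle["normalized"]
    result = rx.clean_cascade(
        normalized, participants, combos=catalogue.combination_products
    )
    expected = brute_cascade_expectations(normalized, participants, catalogue.combination_products)
    got = result.audit.to_frame()
    for exp in expected:
        row = got[got["stage"] == exp["stage"]].iloc[0]
        assert row["n_in"] == exp["n_in"], f"stage {exp['stage']} n_in"
        assert row["n_removed"] == exp["n_removed"], f"stage {exp['stage']} removed"
        assert row["n_out"] == exp["n_out"], f"stage {exp['stage']} n_out"


def test_generator_planted_counts_removed_exactly(sim_bundle, participants, catalogue):
    """Stages 1, 2 and 4 remove exactly the planted violation counts."""
    audit = rx.clean_cascade(
        sim_bundle["normalized"], participants, combos=catalogue.combination_products
    ).audit
    planted = sim_bundle["audit"]
    assert audit.removed(1) == planted["n_empty_name"] + planted["n_unmatched_name"]
    assert audit.removed(2) == planted["n_missing_date"] + planted["n_impossible_date"]
    assert audit.removed(4) == planted["n_post_death"]
    assert audit.removed(3) == -planted["combination_surplus"]
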