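"""Outlier rules, standardization, OLS batteries, BH-FDR and consistent CIs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import brute_bh
from achburden import association as assoc
from achburden import synthetic

TRUTH = synthetic.SimulationTruth(seed=0)


def make_analysis_frame(n, seed, truth=TRUTH):
    """Participants + exposure + latent outcome, aligned for fit_model."""
    parts = synthetic.simulate_participants(n, seed=seed)
    expo = synthetic.simulate_exposure(parts, truth, seed=seed + 1)
    _, g = synthetic.simulate_cognition(
        parts, expo["achb"], truth, seed=seed + 2, polypharmacy=expo["n_nonac"]
    )
    data = parts.copy()
    data["achb"] = expo["achb"].to_numpy()
    data["n_nonac"] = expo["n_nonac"].to_numpy()
    data["ac_count"] = expo["ac_count"].to_numpy()
    data["n_years"] = expo["n_years"].to_numpy().astype(float)
    data["g"] = g.to_numpy()
    return data


class TestDetectOutliers:
    def test_sd_rule_flags_planted_extreme(self):
        rng = np.random.default_rng(1)
        x = np.append(rng.standard_normal(500), 6.0)
        mask = assoc.detect_outliers(x)
        assert mask[-1] and mask.sum() == 1

    def test_zeroes_never_flagged_in_zero_inflated_variables(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([np.zeros(900), rng.gamma(2, 2, size=100), [80.0]])
        mask = assoc.detect_outliers(x, zero_inflated=True)
        assert not mask[:900].any()
        assert mask[-1]

    def test_sd_and_iqr_agree_on_symmetric_sample(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(2000)
        x = np.append(base, 25.0)
        sd_mask = assoc.detect_outliers(x, skew_threshold=np.inf)  # force SD rule
        iqr_mask = assoc.detect_outliers(x, skew_threshold=-1.0)  # force IQR rule
        np.testing.assert_array_equal(sd_mask, iqr_mask)

    def test_constant_vector_yields_empty_mask(self):
        assert not assoc.detect_outliers(np.ones(50)).any()

    def test_missing_values_never_flagged(self):
        x = np.array([0.0, 1.0, np.nan, 2.0, 100.0])
        mask = assoc.detect_outliers(x)
        assert not mask[2]


class TestStandardize:
    def test_example(self):
        np.testing.assert_allclose(
            assoc.standardize(np.array([1.0, 2.0, 3.0])), [-1.224744871, 0.0, 1.224744871]
        )

    def test_constant_raises_with_name(self):
        with pytest.raises(ValueError, match="bmi"):
            assoc.standardize(np.full(10, 3.0), name="bmi")

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        z = assoc.standardize(rng.normal(5, 3, 100))
        np.testing.assert_allclose(assoc.standardize(z), z, atol=1e-12)


class TestBenjaminiHochberg:
    def test_textbook_example(self):
        results = [
            assoc.AssociationResult("x", f"y{i}", 0.1, 0.05, p, 100, "t") for i, p in enumerate([0.01, 0.02, 0.03, 0.04])
        ]
        adj = assoc.adjust_fdr(results)
        assert [r.p_fdr for r in adj] == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_test_unchanged(self):
        [r] = assoc.adjust_fdr([assoc.AssociationResult("x", "y", 0.1, 0.05, 0.03, 100, "t")])
        assert r.p_fdr == pytest.approx(0.03)

    @pytest.mark.parametrize("m", [1, 3, 7, 20])
    def test_matches_bruteforce_stepup_on_random_vectors(self, m):
        rng = np.random.default_rng(m)
        for _ in range(50):
            ps = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            results = [assoc.AssociationResult("x", f"y{i}", 0.0, 1.0, p, 10, "t") for i, p in enumerate(ps)]
            adj = assoc.adjust_fdr(results)
            _, expected = brute_bh(ps)
            np.testing.assert_allclose([r.p_fdr for r in adj], expected, atol=1e-12)

    def test_ci_excludes_zero_iff_fdr_significant(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            m = rng.integers(2, 15)
            betas = rng.normal(0, 0.2, size=m)
            ses = rng.uniform(0.02, 0.1, size=m)
            ps = 2 * stats.norm.sf(np.abs(betas / ses))
            results = [
                assoc.AssociationResult("x", f"y{i}", b, s, p, 100, "t")
                for i, (b, s, p) in enumerate(zip(betas, ses, ps))
            ]
            for r in assoc.adjust_fdr(results, level=0.05):
                assert (r.ci_low > 0 or r.ci_high < 0) == (r.p_fdr <= 0.05)

    def test_empty_family_noop(self):
        assert assoc.adjust_fdr([]) == []


class TestFitModel:
    def test_recovers_planted_effect(self):
        data = make_analysis_frame(20_000, seed=50)
        r = assoc.fit_model("g", "achb", assoc.scale_template(True), data)
        assert r.beta == pytest.approx(TRUTH.beta_achb_g, abs=0.02)
        assert r.n > 15_000
        assert r.template == "scale_model_1.0"

    def test_null_predictor_p_values_uniform(self):
        """Under a null predictor the rejection rate sits at the nominal level."""
        null = synthetic.SimulationTruth(beta_achb_g=0.0, beta_polypharmacy_g=0.0)
        rng = np.random.default_rng(0)
        hits = 0
        reps = 60
        for i in range(reps):
            data = make_analysis_frame(700, seed=1000 + 7 * i, truth=null)
            r = assoc.fit_model("g", "achb", assoc.scale_template(True), data, min_cases_margin=10)
            hits += r.p < 0.05
        assert stats.binomtest(hits, reps, 0.05).pvalue > 1e-3

    def test_polypharmacy_adjustment_attenuates_confounded_effect(self):
        data = make_analysis_frame(10_000, seed=60)
        adj = assoc.fit_model("g", "achb", assoc.scale_template(True), data)
        unadj = assoc.fit_model("g", "achb", assoc.scale_template(False), data)
        assert abs(adj.beta) < abs(unadj.beta)

    def test_standardized_beta_invariant_to_rescaling(self):
        data = make_analysis_frame(3000, seed=70)
        r1 = assoc.fit_model("g", "achb", assoc.scale_template(True), data)
        scaled = data.assign(achb=data["achb"] * 37.0, bmi=data["bmi"] / 5.0, g=data["g"] * 2.0)
        r2 = assoc.fit_model("g", "achb", assoc.scale_template(True), scaled)
        assert r1.beta == pytest.approx(r2.beta, abs=1e-10)
        assert r1.se == pytest.approx(r2.se, abs=1e-10)

    def test_rank_deficiency_reported(self):
        data = make_analysis_frame(1000, seed=80)
        data["bmi"] = data["age"] * 2.0 + 1.0  # exact collinearity
        with pytest.raises(assoc.RankDeficiencyError, match="collinear"):
            assoc.fit_model("g", "achb", assoc.scale_template(True), data)

    def test_missing_column_error_before_fit(self):
        data = make_analysis_frame(1000, seed=90).drop(columns=["bmi"])
        with pytest.raises(KeyError, match="bmi"):
            assoc.fit_model("g", "achb", assoc.scale_template(True), data)

    def test_too_few_cases(self):
        data = make_analysis_frame(1000, seed=95).head(60)
        with pytest.raises(ValueError, match="complete cases"):
            assoc.fit_model("g", "achb", assoc.scale_template(True), data)


class TestPolypharmacyTemplates:
    def test_polypharmacy_as_predictor(self):
        data = make_analysis_frame(5000, seed=130)
        r = assoc.fit_model("g", "n_nonac", assoc.polypharmacy_template(), data)
        assert r.template == "polypharmacy_1.1"
        assert r.beta < 0  # direct planted polypharmacy effect

    def test_plus_variant_controls_anticholinergic_count(self):
        data = make_analysis_frame(5000, seed=140)
        r = assoc.fit_model("g", "n_nonac", assoc.polypharmacy_template(plus=True), data)
        assert r.template == "polypharmacy_plus_1.2"
        assert "ac_count" in assoc.polypharmacy_template(plus=True).covariates


class TestInteractionModel:
    def test_recovers_planted_product_term(self):
        rng = np.random.default_rng(5)
        data = make_analysis_frame(20_000, seed=100)
        z = lambda v: (v - v.mean()) / v.std()
        prod = z(data["achb"]) * z(data["age"])
        data["g"] = data["g"] + 0.1 * prod + 0.0 * rng.standard_normal(len(data))
        r = assoc.interaction_model("g", "achb", data, assoc.scale_template(True), moderator="age")
        assert r.predictor == "achb:age"
        assert r.beta == pytest.approx(0.1, abs=0.02)

    def test_no_interaction_null(self):
        data = make_analysis_frame(8000, seed=110)
        r = assoc.interaction_model("g", "achb", data, assoc.scale_template(True), moderator="age")
        assert abs(r.beta) < 0.05

    def test_constant_moderator_errors(self):
        data = make_analysis_frame(1000, seed=120)
        data["age"] = 55.0
        with pytest.raises(ValueError):
            assoc.interaction_model("g", "achb", data, assoc.scale_template(True), moderator="age")


class TestScaleSizeCorrelation:
    def test_proportional_effects_detected(self):
        sizes = {f"s{i}": i + 3 for i in range(15)}
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {"scale": list(sizes), "beta": [-0.01 * sizes[s] + rng.normal(0, 0.005) for s in sizes]}
        )
        r, p = assoc.scale_size_correlation(df, sizes)
        assert r > 0.8 and p < 0.001

    def test_too_few_scales(self):
        df = pd.DataFrame({"scale": ["a", "b"], "beta": [0.1, 0.2]})
        with pytest.raises(ValueError):
            assoc.scale_size_correlation(df, {"a": 1, "b": 2})

    def test_identical_sizes_undefined(self):
        df = pd.DataFrame({"scale": list("abc"), "beta": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="zero variance"):
            assoc.scale_size_correlation(df, {"a": 5, "b": 5, "c": 5})


@pytest.fixture(scope="module")
def master():
    data = make_analysis_frame(4000, seed=200)
    rng = np.random.default_rng(7)
    # two synthetic scales: the second measures the exposure, the first adds noise
    data["achb_s2"] = data["achb"]
    data["achb_s1"] = 0.5 * data["achb"] + rng.gamma(2, 1, len(data))
    for s in ("s1", "s2"):
        data[f"nonac_{s}"] = data["n_nonac"]
    return data


class TestRunBattery:
    def test_families_and_best_scale(self, master):
        out = assoc.run_battery(master, ["s1", "s2"])
        assert out.best_scale == "s2"
        df = out.frame("scales_g")
        assert set(df["scale"]) == {"s1", "s2"}
        assert (df["p_fdr"] >= df["p"] - 1e-15).all()

    def test_single_model_family_reduces_to_identity_fdr(self, master):
        out = assoc.run_battery(master, ["s2"])
        df = out.frame("scales_g")
        assert len(df) == 1
        assert df.loc[0, "p_fdr"] == pytest.approx(df.loc[0, "p"])

    def test_missing_inputs_rejected_before_any_fit(self, master):
        with pytest.raises(KeyError, match="achb_s3"):
            assoc.run_battery(master, ["s3"])


def test_sensitivity_one_year_requires_records_in_window():
    parts = synthetic.simulate_participants(50, seed=1)
    rec = pd.DataFrame(
        {
            "participant_id": parts["participant_id"].head(5),
            "issue_date": pd.Timestamp("1990-01-01"),
            "drug_generic": "a",
            "route": "oral",
            "supplier": "s",
            "year": 1990,
        }
    )
    scale = __import__("achburden").achb.AnticholinergicScale(name="s", potencies={"a": 1.0})
    with pytest.raises(ValueError, match="one-year"):
        assoc.sensitivity_one_year(rec, parts, [scale], parts.copy())
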