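"""Standardized linear-model batteries with FDR control.

Every association is an ordinary-least-squares fit of a standardized
outcome on a standardized predictor plus a template-defined covariate set,
reported as the predictor's standardized coefficient (beta), its SE, a
standard-normal two-sided p-value, the Benjamini–Hochberg FDR-adjusted
p-value within the model family, and a confidence interval whose level is
tied to the family's BH-consistent critical p-value

    half-width = z(1 - p_crit/2) * SE,   p_crit = k* . alpha / m,

so that "CI excludes zero" agrees with "FDR-significant" by construction.

Outliers are removed before model fitting: values 4 or more SDs from the
mean for roughly symmetric variables, 4 or more IQRs from the median for
skewed ones (|skewness| > 1), and for zero-inflated variables (burden and
prescription counts) the zeroes are set aside before computing bounds and
are never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import OLS
from statsmodels.stats.multitest import multipletests

#: Covariates shared by every model (cognitive and imaging).
BASE_COVARIATES: tuple[str, ...] = (
    "age",
    "n_years",
    "supplier",
    "deprivation",
    "smoking",
    "alcohol",
    "activity",
    "bmi",
    "apoe",
    "comorbidity_count",
    "history_mood",
    "history_anxiety",
    "history_schizophrenia",
    "history_diabetes",
    "history_hypercholesterolemia",
    "history_hypertension",
    "history_mi",
)

#: Extra covariates for imaging outcomes (derived age terms, scanner head
#: position, ethnicity and assessment centre).
IMAGING_EXTRA_COVARIATES: tuple[str, ...] = (
    "sex",
    "age_sq",
    "age_x_sex",
    "agesq_x_sex",
    "head_pos_x",
    "head_pos_y",
    "head_pos_z",
    "ethnicity",
    "assessment_centre",
)

#: Column-name prefixes treated as zero-inflated for outlier detection.
ZERO_INFLATED_PREFIXES = ("achb", "nonac_", "count_", "total_rx", "ac_count", "n_nonac")


class RankDeficiencyError(np.linalg.LinAlgError):
    """Raised when the design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelTemplate:
    """A named covariate set with a declared predictor role."""

    name: str
    predictor_role: str  # "achb" or "polypharmacy"
    covariates: tuple[str, ...]
    imaging_extras: bool = False


def scale_template(
    adjust_polypharmacy: bool = True,
    polypharmacy_col: str = "n_nonac",
    imaging: bool = False,
) -> ModelTemplate:
    """Scale model: AChB predictor, full covariate set.

    With ``adjust_polypharmacy`` the per-scale non-anticholinergic
    prescription count enters as a covariate (the fully adjusted model);
    without it, results are "before adjustment for polypharmacy".
    """
    cov = BASE_COVARIATES + ((polypharmacy_col,) if adjust_polypharmacy else ())
    if imaging:
        cov = cov + IMAGING_EXTRA_COVARIATES
    suffix = "" if adjust_polypharmacy else "_unadjusted"
    return ModelTemplate(
        name=("imaging_2.0" if imaging else "scale_model_1.0") + suffix,
        predictor_role="achb",
        covariates=cov,
        imaging_extras=imaging,
    )


def polypharmacy_template(plus: bool = False, ac_count_col: str = "ac_count") -> ModelTemplate:
    """Polypharmacy as main predictor; ``plus`` adds the anticholinergic count."""
    cov = BASE_COVARIATES + ((ac_count_col,) if plus else ())
    return ModelTemplate(
        name="polypharmacy_plus_1.2" if plus else "polypharmacy_1.1",
        predictor_role="polypharmacy",
        covariates=cov,
    )


@dataclass
class AssociationResult:
    """One predictor→outcome model: standardized beta and its inference."""

    predictor: str
    outcome: str
    beta: float
    se: float
    p: float
    n: int
    template: str
    p_fdr: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    extra: dict = field(default_factory=dict)


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results]).drop(columns=["extra"])


def _skewness(x: np.ndarray) -> float:
    """Biased (moment) sample skewness, as scipy.stats.skew(bias=True)."""
    m = x.mean()
    s2 = np.mean((x - m) ** 2)
    if s2 == 0:
        return 0.0
    return float(np.mean((x - m) ** 3) / s2**1.5)


def detect_outliers(
    values: np.ndarray | pd.Series,
    skew_threshold: float = 1.0,
    zero_inflated: bool = False,
    k: float = 4.0,
) -> np.ndarray:
    """Boolean mask of outliers (True = flagged).

    Symmetric variables (|skewness| <= *skew_threshold*) use the SD rule
    (|x − mean| >= k·SD); skewed ones the IQR rule (outside
    median ± k·IQR).  For zero-inflated variables the zeroes are excluded
    before computing bounds and are never flagged.  Missing values are
    never flagged.  All-constant input yields an empty mask.
    """
    x = np.asarray(values, dtype=float)
    mask = np.zeros(x.shape, dtype=bool)
    valid = ~np.isnan(x)
    ref = valid & (x != 0) if zero_inflated else valid
    xr = x[ref]
    if xr.size < 3 or xr.std() == 0:
        return mask
    if abs(_skewness(xr)) <= skew_threshold:
        lo, hi = xr.mean() - k * xr.std(), xr.mean() + k * xr.std()
    else:
        med = np.median(xr)
        iqr = np.subtract(*np.percentile(xr, [75, 25]))
        if iqr == 0:
            return mask
        lo, hi = med - k * iqr, med + k * iqr
    flagged = ref & ((x < lo) | (x > hi))
    mask[flagged] = True
    return mask


def standardize(values: np.ndarray | pd.Series, name: str = "variable") -> np.ndarray:
    """Z-scores: mean 0, SD 1 (population SD of the analysis sample)."""
    x = np.asarray(values, dtype=float)
    sd = np.nanstd(x)
    if sd == 0 or np.isnan(sd):
        raise ValueError(f"cannot standardize {name!r}: zero variance")
    return (x - np.nanmean(x)) / sd


def _is_binary(s: pd.Series) -> bool:
    return s.dropna().nunique() <= 2


def add_imaging_terms(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    male = (df["sex"].astype(str) == "male").astype(float) if "sex" in df else 0.0
    df["age_sq"] = df["age"] ** 2
    df["age_x_sex"] = df["age"] * male
    df["agesq_x_sex"] = df["age"] ** 2 * male
    return df


def _design_matrix(df: pd.DataFrame, cols: list[str], require: set[str] | None = None) -> pd.DataFrame:
    """Numeric design: standardized continuous, 0/1 binaries, dummy contrasts
    with the most frequent level as reference.

    Covariates with no variation on the analysis sample carry no information
    and are dropped; columns in *require* (predictor, moderator) must vary
    and raise instead.
    """
    require = require or set()
    out: dict[str, np.ndarray] = {}
    for c in cols:
        s = df[c]
        if c not in require and s.nunique(dropna=True) <= 1:
            continue
        if s.dtype == bool:
            out[c] = s.to_numpy(dtype=float)
        elif pd.api.types.is_numeric_dtype(s):
            out[c] = s.to_numpy(dtype=float) if _is_binary(s) else standardize(s, name=c)
        else:
            vals = s.astype(str).to_numpy()
            levels, counts = np.unique(vals, return_counts=True)
            ref = levels[np.argmax(counts)]
            for level in levels:
                if level == ref:
                    continue
                out[f"{c}[{level}]"] = (vals == level).astype(float)
    return pd.DataFrame(out, index=df.index)


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy()])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        bad = np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max()
        names = ["const"] + list(X.columns)
        collinear = [names[i] for i in np.flatnonzero(bad)]
        raise RankDeficiencyError(f"design matrix is rank deficient; collinear columns: {collinear}")


def fit_model(
    outcome: str,
    predictor: str,
    template: ModelTemplate,
    data: pd.DataFrame,
    remove_outliers: bool = True,
    zero_inflated_vars: tuple[str, ...] | None = None,
    interaction_with: str | None = None,
    min_cases_margin: int = 50,
) -> AssociationResult:
    """OLS of standardized *outcome* on standardized *predictor* + covariates.

    Pipeline per model: flag and drop outliers on the numeric variables,
    restrict to complete cases, standardize, fit.  With *interaction_with*,
    a product term of the (standardized) predictor and moderator is added
    and the returned result describes the product term.
    """
    cols = [outcome, predictor] + [c for c in template.covariates if c not in (outcome, predictor)]
    if interaction_with is not None and interaction_with not in cols:
        cols.append(interaction_with)
    if template.imaging_extras:
        need = {"age", "sex"} | set(cols) - {"age_sq", "age_x_sex", "agesq_x_sex"}
    else:
        need = set(cols)
    missing = sorted(c for c in need if c not in data.columns and c not in ("age_sq", "age_x_sex", "agesq_x_sex"))
    if missing:
        raise KeyError(f"data lacks required column(s) {missing}")
    df = add_imaging_terms(data) if template.imaging_extras and "age_sq" not in data.columns else data
    df = df[list(dict.fromkeys(cols))].copy()

    if remove_outliers:
        zi = ZERO_INFLATED_PREFIXES if zero_inflated_vars is None else zero_inflated_vars
        drop = np.zeros(len(df), dtype=bool)
        for c in df.columns:
            s = df[c]
            if pd.api.types.is_numeric_dtype(s) and s.dtype != bool and not _is_binary(s):
                drop |= detect_outliers(s, zero_inflated=any(str(c).startswith(p) for p in zi))
        df = df[~drop]
    df = df.dropna()

    y = standardize(df[outcome], name=outcome)
    xcols = [predictor] + [c for c in df.columns if c not in (outcome, predictor)]
    must_vary = {predictor} | ({interaction_with} if interaction_with else set())
    X = _design_matrix(df, xcols, require=must_vary)
    pred_col = predictor
    if interaction_with is not None:
        prod = f"{predictor}:{interaction_with}"
        X[prod] = X[predictor] * X[interaction_with]
        pred_col = prod
    n = len(df)
    if n < min_cases_margin + X.shape[1] + 1:
        raise ValueError(f"too few complete cases ({n}) for {X.shape[1] + 1} parameters")
    _check_rank(X)
    design = X.copy()
    design.insert(0, "const", 1.0)
    fit = OLS(y, design).fit()
    beta = float(fit.params[pred_col])
    se = float(fit.bse[pred_col])
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    extra = {"params": fit.params.to_dict()} if interaction_with else {}
    return AssociationResult(
        predictor=pred_col, outcome=outcome, beta=beta, se=se, p=p, n=n, template=template.name, extra=extra
    )


def interaction_model(
    outcome: str,
    predictor: str,
    data: pd.DataFrame,
    template: ModelTemplate,
    moderator: str = "age",
    **kwargs,
) -> AssociationResult:
    """Product-term model: both terms standardized before forming the product."""
    return fit_model(outcome, predictor, template, data, interaction_with=moderator, **kwargs)


def adjust_fdr(results: list[AssociationResult], level: float = 0.05) -> list[AssociationResult]:
    """Benjamini–Hochberg adjustment within one family + FDR-consistent CIs.

    The CI level derives from the family's BH critical p-value
    ``p_crit = k*·level/m`` (``level/m`` when nothing is rejected), so a CI
    excludes zero exactly when the FDR-adjusted p-value falls below
    *level*.
    """
    if not results:
        return results
    ps = np.array([r.p for r in results])
    reject, p_adj, _, _ = multipletests(ps, alpha=level, method="fdr_bh")
    m = len(ps)
    k = int(reject.sum())
    p_crit = (k if k > 0 else 1) * level / m
    zcrit = stats.norm.ppf(1 - p_crit / 2)
    out = []
    for r, pa in zip(results, p_adj):
        out.append(replace(r, p_fdr=float(pa), ci_low=r.beta - zcrit * r.se, ci_high=r.beta + zcrit * r.se))
    return out


def scale_size_correlation(
    results: pd.DataFrame,
    scale_sizes: dict[str, int],
    beta_col: str = "beta",
    scale_col: str = "scale",
) -> tuple[float, float]:
    """Pearson correlation between scale drug-count and |beta| across scales."""
    if len(results) < 3:
        raise ValueError("need at least 3 scales to correlate size with effect")
    sizes = np.array([scale_sizes[s] for s in results[scale_col]], dtype=float)
    abs_beta = results[beta_col].abs().to_numpy()
    if np.std(sizes) == 0 or np.std(abs_beta) == 0:
        raise ValueError("scale sizes or effects have zero variance; correlation undefined")
    r, p = stats.pearsonr(sizes, abs_beta)
    return float(r), float(p)


@dataclass
class BatteryResult:
    """Tidy per-family result tables plus the selected (strongest) scale."""

    families: dict[str, pd.DataFrame]
    best_scale: str | None = None

    def frame(self, family: str) -> pd.DataFrame:
        return self.families[family]


def run_battery(
    master: pd.DataFrame,
    scale_names: list[str],
    g_col: str = "g",
    level: float = 0.05,
    adjust_polypharmacy: bool = True,
    class_cols: dict[str, list[str]] | None = None,
    test_cols: list[str] | None = None,
    imaging_outcomes: dict[str, list[str]] | None = None,
    brain_outcome: str | None = None,
    **fit_kwargs,
) -> BatteryResult:
    """Run the model families on an aligned participant-level master table.

    Families (each FDR-adjusted separately): per-scale AChB → g
    (``scales_g``); per-scale AChB → brain (``scales_brain``); per-class
    AChB → g / brain for the strongest scale (``classes_g`` /
    ``classes_brain``); AChB → each cognitive test (``tests``); AChB → each
    imaging outcome family given in *imaging_outcomes*.  The strongest
    scale is the one with maximal |beta| in ``scales_g``.

    *master* must contain ``achb_<scale>`` and ``nonac_<scale>`` columns for
    each scale, the latent outcome *g_col*, and the template covariates.
    """
    required = [g_col] + [f"achb_{s}" for s in scale_names] + [f"nonac_{s}" for s in scale_names]
    missing = [c for c in required if c not in master.columns]
    if missing:
        raise KeyError(f"master table lacks column(s) {missing}")

    families: dict[str, list[AssociationResult]] = {}

    def scale_tmpl(s: str, imaging: bool = False) -> ModelTemplate:
        return scale_template(adjust_polypharmacy=adjust_polypharmacy, polypharmacy_col=f"nonac_{s}", imaging=imaging)

    res = []
    for s in scale_names:
        r = fit_model(g_col, f"achb_{s}", scale_tmpl(s), master, **fit_kwargs)
        r.extra["scale"] = s
        res.append(r)
    families["scales_g"] = res
    best_idx = int(np.argmax([abs(r.beta) for r in res]))
    best_scale = scale_names[best_idx]

    if adjust_polypharmacy:
        # results "before adjustment for polypharmacy", reported alongside
        families["scales_g_unadjusted"] = [
            fit_model(g_col, f"achb_{s}", scale_template(adjust_polypharmacy=False), master, **fit_kwargs)
            for s in scale_names
        ]

    if brain_outcome is not None and brain_outcome in master.columns:
        families["scales_brain"] = [
            fit_model(brain_outcome, f"achb_{s}", scale_tmpl(s, imaging=True), master, **fit_kwargs)
            for s in scale_names
        ]

    if class_cols:
        for fam, cols in class_cols.items():
            families[f"classes_{fam}"] = [
                fit_model(
                    g_col if fam == "g" else brain_outcome,
                    c,
                    scale_tmpl(best_scale, imaging=(fam != "g")),
                    master,
                    **fit_kwargs,
                )
                for c in cols
            ]

    if test_cols:
        families["tests"] = [
            fit_model(t, f"achb_{best_scale}", scale_tmpl(best_scale), master, **fit_kwargs) for t in test_cols
        ]

    if imaging_outcomes:
        for fam, cols in imaging_outcomes.items():
            families[fam] = [
                fit_model(c, f"achb_{best_scale}", scale_tmpl(best_scale, imaging=True), master, **fit_kwargs)
                for c in cols
            ]

    adjusted = {fam: results_to_frame(adjust_fdr(rs, level=level)) for fam, rs in families.items()}
    for fam in ("scales_g", "scales_g_unadjusted"):
        if fam in adjusted:
            df = adjusted[fam].copy()
            df["scale"] = scale_names
            adjusted[fam] = df
    return BatteryResult(families=adjusted, best_scale=best_scale)


def sensitivity_one_year(
    records_pre_assessment: pd.DataFrame,
    participants: pd.DataFrame,
    scales: list,
    master: pd.DataFrame,
    g_col: str = "g",
    level: float = 0.05,
    **battery_kwargs,
) -> BatteryResult:
    """Rerun the scale family with burden from the year preceding assessment.

    The main pipeline's assessment-proximity exclusion is inverted: only
    records dated within 365 days before the assessment contribute.
    """
    from achburden.achb import build_burden_table

    assess = participants.set_index("participant_id")["assessment_date"]
    rec = records_pre_assessment.copy()
    ad = pd.to_datetime(rec["participant_id"].map(assess))
    dates = pd.to_datetime(rec["issue_date"])
    rec = rec[(dates >= ad - pd.Timedelta(days=365)) & (dates < ad)]
    if rec.empty:
        raise ValueError("no prescriptions fall in the one-year pre-assessment window")
    burden = build_burden_table(rec, scales, participants=participants)
    keep = [c for c in master.columns if not (c.startswith("achb_") or c.startswith("nonac_") or c.startswith("count_"))]
    merged = master[keep].merge(burden.drop(columns=["total_rx", "n_years"], errors="ignore"), on="participant_id")
    return run_battery(merged, [s.name for s in scales], g_col=g_col, level=level, **battery_kwargs)
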