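"""Seeded synthetic-data generators with planted ground truth.

Real primary-care prescription data are access-controlled, so the package
ships generators that emulate the statistical structure the analysis
assumes: a drug catalogue with brands, combination products and ATC codes;
anticholinergic scales of varying coverage; confounded, zero-inflated
prescription streams with planted cleaning violations; a latent-factor
cognitive battery with a planted burden effect; and imaging phenotypes with
planted null effects.  Every generator is deterministic under its seed and
returns enough bookkeeping (a violation audit, a truth record) for
downstream stages to be checked exactly.

Covariate distributions are stylized (uniform ages, simple categoricals)
rather than matched to any cohort: acceptance of the analysis code rests on
parameter recovery under known truth, not on demographic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from achburden.achb import AnticholinergicScale

ATC_LEVEL1_LETTERS = "ABCDGHJLMNPRSV"

ROUTE_CLASSES = ("oral", "ophthalmic", "otic", "nasal", "topical", "parenteral")

#: Default per-test standardized factor loadings of the cognitive battery.
#: Mean squared loading ~0.26, in the range reported for large middle-aged
#: cohorts tested with brief batteries.
DEFAULT_LOADINGS: dict[str, float] = {
    "pairs_matching": 0.45,
    "reaction_time": 0.40,
    "numeric_memory": 0.55,
    "prospective_memory": 0.35,
    "fluid_intelligence": 0.65,
    "trail_making_b": 0.50,
    "matrix_completion": 0.60,
    "symbol_digit": 0.55,
    "tower_rearranging": 0.45,
}

#: Test reported as pass/fail; generated by thresholding its latent score.
BINARY_TEST = "prospective_memory"

#: Tests administered only at the second (imaging) visit.
VISIT2_ONLY_TESTS = frozenset({"trail_making_b", "matrix_completion", "symbol_digit", "tower_rearranging"})

DEFAULT_RESIDUAL_CORRELATIONS: list[tuple[str, str, float]] = [
    ("trail_making_b", "symbol_digit", 0.20),
    ("pairs_matching", "numeric_memory", 0.15),
]

#: covariate -> (effect on exposure propensity, standardized effect on g)
DEFAULT_CONFOUNDER_EFFECTS: dict[str, tuple[float, float]] = {
    "age": (0.35, -0.30),
    "comorbidity_count": (0.45, -0.10),
}


class ConfigurationError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass(frozen=True)
class SimulationTruth:
    """Planted parameters of one simulation, kept for recovery checks.

    ``beta_achb_g`` is the standardized effect of cumulative burden on
    latent g; ``beta_achb_brain`` the (default null) standardized effect on
    each imaging outcome.  ``beta_polypharmacy_g`` is a direct effect of
    non-anticholinergic prescription count on g: because polypharmacy is
    correlated with burden given the observed covariates, it induces the
    configured attenuation of the burden coefficient once adjusted for.
    """

    beta_achb_g: float = -0.2
    beta_achb_brain: float = 0.0
    beta_polypharmacy_g: float = -0.22  # default tuned so adjusting for
    # polypharmacy attenuates the burden coefficient by ~30%
    loadings: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    residual_correlations: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_RESIDUAL_CORRELATIONS)
    )
    confounder_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_EFFECTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, b in (("beta_achb_g", self.beta_achb_g), ("beta_achb_brain", self.beta_achb_brain)):
            if not abs(b) < 1:
                raise ConfigurationError(f"{name} must satisfy |beta| < 1, got {b}")
        for test, lam in self.loadings.items():
            if not 0 < lam < 1:
                raise ConfigurationError(f"loading for {test!r} must lie in (0, 1), got {lam}")

    def to_dict(self) -> dict:
        return {
            "beta_achb_g": self.beta_achb_g,
            "beta_achb_brain": self.beta_achb_brain,
            "beta_polypharmacy_g": self.beta_polypharmacy_g,
            "loadings": self.loadings,
            "residual_correlations": [list(t) for t in self.residual_correlations],
            "confounder_effects": {k: list(v) for k, v in self.confounder_effects.items()},
            "seed": self.seed,
        }


@dataclass(frozen=True)
class DrugCatalogue:
    """The drug universe: generics, brand aliases, ATC codes, routes, rates.

    ``entries`` has one row per generic: ``generic``, ``atc_code`` (7-char
    WHO-style code), ``routes`` (tuple, first = most common), ``base_rate``
    (expected prescriptions/participant-year) and ``brands`` (tuple of
    aliases).  ``combination_products`` maps a product name to its ≥2
    generic components.
    """

    entries: pd.DataFrame
    combination_products: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entries["generic"].duplicated().any():
            raise ConfigurationError("generic names must be unique")
        for code in self.entries["atc_code"]:
            if len(code) != 7 or code[0] not in ATC_LEVEL1_LETTERS or not code[1:3].isdigit() or not code[3].isalpha():
                raise ConfigurationError(f"malformed ATC code {code!r}")
        generics = set(self.entries["generic"])
        for product, comps in self.combination_products.items():
            if len(comps) < 2:
                raise ConfigurationError(f"combination {product!r} needs >= 2 components")
            missing = set(comps) - generics
            if missing:
                raise ConfigurationError(f"combination {product!r} has unknown components {sorted(missing)}")

    @property
    def generics(self) -> list[str]:
        return list(self.entries["generic"])

    @property
    def formulary(self) -> set[str]:
        """Names that normalization may resolve to: generics + combination products."""
        return set(self.entries["generic"]) | set(self.combination_products)

    @property
    def brand_map(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for generic, brands in zip(self.entries["generic"], self.entries["brands"]):
            for b in brands:
                out[b] = generic
        return out

    @property
    def atc_map(self) -> pd.DataFrame:
        return self.entries[["generic", "atc_code"]].copy()


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_catalogue(n_drugs: int, n_combinations: int, seed: int) -> DrugCatalogue:
    """Generate a synthetic drug catalogue.

    Guarantees at least one drug per route class, brand aliases for a fifth
    of the drugs, and ATC codes spanning several anatomical main groups.
    """
    if n_drugs < 10:
        raise ValueError(f"n_drugs must be >= 10, got {n_drugs}")
    if n_combinations > n_drugs / 2:
        raise ConfigurationError(f"n_combinations ({n_combinations}) exceeds n_drugs/2 ({n_drugs / 2})")
    rng = _rng(seed)
    letters = "ABCDGHJMNR"  # 10 anatomical main groups
    rows = []
    alpha = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
    for i in range(n_drugs):
        generic = f"drug{i:03d}"
        letter = letters[i % len(letters)]
        code = f"{letter}{(i // len(letters)) % 16 + 1:02d}{rng.choice(alpha)}{rng.choice(alpha)}{rng.integers(1, 100):02d}"
        routes = ["oral"]
        if i < len(ROUTE_CLASSES):  # every route class represented
            routes = [ROUTE_CLASSES[i]] if ROUTE_CLASSES[i] != "oral" else ["oral"]
            if routes != ["oral"]:
                routes = ["oral", ROUTE_CLASSES[i]]
        elif rng.random() < 0.15:
            routes = ["oral", str(rng.choice(ROUTE_CLASSES[1:]))]
        n_brands = 2 if i % 4 == 0 else (1 if i % 4 == 1 else 0)  # >=25% with 2 aliases
        brands = tuple(f"brand{i:03d}{chr(97 + k)}" for k in range(n_brands))
        rows.append(
            {
                "generic": generic,
                "atc_code": code,
                "routes": tuple(routes),
                "base_rate": float(rng.gamma(1.2, 0.25)),
                "brands": brands,
            }
        )
    entries = pd.DataFrame(rows)
    combos: dict[str, list[str]] = {}
    for j in range(n_combinations):
        k = int(rng.integers(2, 4))
        comps = list(rng.choice(entries["generic"], size=k, replace=False))
        combos[f"combo{j:02d}"] = comps
    return DrugCatalogue(entries=entries, combination_products=combos)


def make_scales(
    catalogue: DrugCatalogue,
    n_scales: int = 15,
    coverage_range: tuple[float, float] = (0.05, 0.40),
    seed: int = 0,
) -> list[AnticholinergicScale]:
    """Generate anticholinergic scales of graded drug coverage.

    Coverage fractions are spread evenly across *coverage_range*; potencies
    are drawn from {1, 2, 3}.  The largest scale carries improbable-action
    entries (to exercise the 0.5 rule) and is flagged as modified.
    """
    if len(catalogue.entries) == 0:
        raise ValueError("catalogue is empty")
    lo, hi = coverage_range
    if not (0 < lo <= hi <= 1):
        raise ValueError(f"coverage_range must satisfy 0 < low <= high <= 1, got {coverage_range}")
    rng = _rng(seed)
    n = len(catalogue.entries)
    coverages = np.linspace(lo, hi, n_scales)
    # Scales share a common core, as published scales do (drugs with
    # undisputed anticholinergic action appear on every scale; broader
    # scales add progressively more marginal drugs): one consensus ranking
    # per catalogue, each scale listing its top-k.  Potency assignments
    # still differ between scales.
    ranking = rng.permutation(np.asarray(catalogue.generics))
    scales = []
    for i, cov in enumerate(coverages):
        size = max(1, int(round(cov * n)))
        drugs = ranking[:size]
        potencies = {d: float(rng.choice([1, 2, 3])) for d in drugs}
        improbable: frozenset[str] = frozenset()
        modified = False
        if i == n_scales - 1 and size >= 3:
            improbable = frozenset(rng.choice(drugs, size=max(1, size // 3), replace=False))
            modified = True
        scales.append(
            AnticholinergicScale(
                name=f"scale_{i + 1:02d}", potencies=potencies, improbable_set=improbable, modified=modified
            )
        )
    return scales


def simulate_participants(n: int, seed: int) -> pd.DataFrame:
    """Participant table with stylized covariates.

    Ages are Uniform(40, 71); categoricals (sex, smoking, alcohol frequency,
    physical activity, data supplier, APOE carrier class, ethnicity,
    assessment centre) all have nonzero frequencies; a small fraction carry
    death dates and exclusion diagnoses so the cleaning cascade has work to
    do.  A ~12% subset attends a later imaging assessment.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    age = rng.uniform(40, 71, size=n)
    assessment = pd.Timestamp("2006-01-01") + pd.to_timedelta(rng.integers(0, 5 * 365, size=n), unit="D")
    has_imaging = rng.random(n) < 0.12
    imaging_date = assessment + pd.to_timedelta(rng.integers(6 * 365, 10 * 365, size=n), unit="D")
    death = rng.random(n) < 0.03
    death_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    death_date[death] = pd.Timestamp("2006-01-01") + pd.to_timedelta(rng.integers(0, 10 * 365, size=int(death.sum())), unit="D")
    df = pd.DataFrame(
        {
            "participant_id": [f"p{i:06d}" for i in range(n)],
            "age": age,
            "sex": rng.choice(["female", "male"], size=n, p=[0.54, 0.46]),
            "smoking": rng.choice(["non_smoker", "previous", "current"], size=n, p=[0.56, 0.33, 0.11]),
            "alcohol": rng.choice(
                ["daily", "three_four_weekly", "once_twice_weekly", "one_three_monthly", "special_occasions", "never"],
                size=n,
                p=[0.20, 0.23, 0.26, 0.11, 0.11, 0.09],
            ),
            "activity": rng.choice(["mild", "moderate", "strenuous"], size=n, p=[0.35, 0.45, 0.20]),
            "supplier": rng.choice(["england_vision", "england_tpp", "scotland", "wales"], size=n, p=[0.45, 0.35, 0.12, 0.08]),
            "apoe": rng.choice(["e2", "e3", "e4"], size=n, p=[0.13, 0.61, 0.26]),
            "ethnicity": rng.choice(["white", "asian", "black", "mixed", "other"], size=n, p=[0.94, 0.02, 0.02, 0.01, 0.01]),
            "assessment_centre": rng.choice(["cheadle", "newcastle", "reading", "bristol"], size=n),
            "deprivation": rng.gumbel(-1.3, 1.6, size=n).clip(-6.3, 11.0),
            "bmi": rng.normal(27.3, 4.6, size=n).clip(15, 55),
            "comorbidity_count": rng.poisson(1.0 + 0.04 * (age - 40)),
            "assessment_date": assessment,
            "has_imaging": has_imaging,
            "imaging_date": imaging_date.where(has_imaging, pd.NaT),
            "death_date": death_date.to_numpy(),
            "has_exclusion_dx": rng.random(n) < 0.02,
            "birth_year": (2006 - age).astype(int),
        }
    )
    for flag, p in [
        ("history_mood", 0.12),
        ("history_anxiety", 0.08),
        ("history_schizophrenia", 0.005),
        ("history_diabetes", 0.05),
        ("history_hypercholesterolemia", 0.15),
        ("history_hypertension", 0.25),
        ("history_mi", 0.03),
    ]:
        df[flag] = rng.random(n) < p
    return df


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


DEFAULT_VIOLATIONS = {"empty_name": 10, "missing_date": 5, "impossible_date": 5, "post_death": 3, "unmatched_name": 5}


def simulate_prescriptions(
    participants: pd.DataFrame,
    catalogue: DrugCatalogue,
    truth: SimulationTruth,
    years: tuple[int, int] = (2000, 2015),
    seed: int = 0,
    violations: dict[str, int] | None = None,
    brand_fraction: float = 0.2,
    combo_fraction: float = 0.05,
    rate_multiplier: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a confounded prescription stream with planted violations.

    Per participant-year prescription counts are Poisson with a rate that
    increases with age and comorbidity count (the confounding structure in
    ``truth.confounder_effects``), which makes per-participant burden
    zero-inflated and right-skewed.  A configurable number of records are
    planted per violation class — empty drug strings, unmatched names,
    missing/impossible dates, post-death issues — all otherwise clean, so
    each cleaning stage's removal count is exactly predictable.  Returns
    the record table and an audit of planted counts.
    """
    start, end = years
    if start >= end:
        raise ValueError(f"years must satisfy start < end, got {years}")
    rng = _rng(seed)
    viol = dict(DEFAULT_VIOLATIONS if violations is None else violations)
    n = len(participants)
    age_z = _zscore(participants["age"].to_numpy())
    com_z = _zscore(participants["comorbidity_count"].to_numpy())
    a_age = truth.confounder_effects.get("age", (0.0, 0.0))[0]
    a_com = truth.confounder_effects.get("comorbidity_count", (0.0, 0.0))[0]
    total_rate = float(catalogue.entries["base_rate"].sum()) * rate_multiplier
    lam = total_rate * np.exp(a_age * age_z + a_com * com_z - 0.5 * (a_age**2 + a_com**2))
    year_list = np.arange(start, end + 1)
    counts = rng.poisson(lam[:, None], size=(n, len(year_list)))
    # no organic prescriptions after death (post-death records are planted explicitly)
    death_year = pd.to_datetime(participants["death_date"]).dt.year.fillna(9999).to_numpy()
    counts[year_list[None, :] > death_year[:, None]] = 0

    total = int(counts.sum())
    pid = np.repeat(np.repeat(participants["participant_id"].to_numpy(), len(year_list)), counts.ravel())
    supplier = np.repeat(np.repeat(participants["supplier"].to_numpy(), len(year_list)), counts.ravel())
    year = np.repeat(np.tile(year_list, n), counts.ravel())
    death_rep = np.repeat(np.repeat(pd.to_datetime(participants["death_date"]).to_numpy(), len(year_list)), counts.ravel())
    day = rng.integers(0, 365, size=total)
    dates = pd.to_datetime(year.astype(str)) + pd.to_timedelta(day, unit="D")
    # clamp within-death-year organic records to on/before the death date
    over = pd.Series(dates).to_numpy() > death_rep
    if over.any():
        dates = pd.Series(dates)
        dates[over] = pd.to_datetime(death_rep[over]) - pd.to_timedelta(rng.integers(0, 30, size=int(over.sum())), unit="D")
        dates = pd.DatetimeIndex(dates)

    base = catalogue.entries
    rate_sum = float(base["base_rate"].sum())
    p_drug = base["base_rate"].to_numpy() / rate_sum if rate_sum > 0 else np.full(len(base), 1.0 / len(base))
    drug_idx = rng.choice(len(base), size=total, p=p_drug)
    drug = base["generic"].to_numpy()[drug_idx]
    # routes: mostly the drug's primary route, occasionally an alternative
    routes_per_drug = base["routes"].to_numpy()
    route = np.array([r[0] for r in routes_per_drug])[drug_idx]
    alt = rng.random(total) < 0.10
    for i in np.flatnonzero(alt):
        rs = routes_per_drug[drug_idx[i]]
        route[i] = rs[int(rng.integers(0, len(rs)))]
    # brand substitution
    drug_out = drug.astype(object)
    n_brands = np.array([len(b) for b in base["brands"]])[drug_idx]
    use_brand = (rng.random(total) < brand_fraction) & (n_brands > 0)
    for i in np.flatnonzero(use_brand):
        brands = base["brands"].to_numpy()[drug_idx[i]]
        drug_out[i] = brands[int(rng.integers(0, len(brands)))]
    # combination products replace a fraction of records
    n_combo = 0
    combo_surplus = 0
    if catalogue.combination_products:
        combo_names = list(catalogue.combination_products)
        use_combo = rng.random(total) < combo_fraction
        n_combo = int(use_combo.sum())
        picked = rng.choice(combo_names, size=n_combo)
        drug_out[use_combo] = picked
        route[use_combo] = "oral"
        combo_surplus = int(sum(len(catalogue.combination_products[c]) - 1 for c in picked))

    records = pd.DataFrame(
        {"participant_id": pid, "issue_date": pd.DatetimeIndex(dates), "drug_raw": drug_out, "route": route, "supplier": supplier}
    )

    # planted violations: each otherwise clean so it is removed at exactly one stage
    def _clean_base(k: int) -> pd.DataFrame:
        idx = rng.integers(0, n, size=k)
        y = rng.integers(start + 1, end, size=k)  # not first year, inside window
        d = pd.to_datetime(y.astype(str)) + pd.to_timedelta(rng.integers(0, 365, size=k), unit="D")
        return pd.DataFrame(
            {
                "participant_id": participants["participant_id"].to_numpy()[idx],
                "issue_date": d,
                "drug_raw": rng.choice(base["generic"], size=k),
                "route": "oral",
                "supplier": participants["supplier"].to_numpy()[idx],
            }
        )

    planted = []
    k = viol.get("empty_name", 0)
    if k:
        p = _clean_base(k)
        p["drug_raw"] = ""
        planted.append(p)
    k = viol.get("unmatched_name", 0)
    if k:
        p = _clean_base(k)
        p["drug_raw"] = "xyzzy-compound"
        planted.append(p)
    k = viol.get("missing_date", 0)
    if k:
        p = _clean_base(k)
        p["issue_date"] = pd.NaT
        planted.append(p)
    k = viol.get("impossible_date", 0)
    if k:
        p = _clean_base(k)
        future = np.arange(k) % 2 == 0
        p.loc[future, "issue_date"] = pd.Timestamp("2200-01-01")
        p.loc[~future, "issue_date"] = pd.Timestamp("1850-01-01")
        planted.append(p)
    k = viol.get("post_death", 0)
    n_post_death = 0
    if k:
        dead = participants[pd.to_datetime(participants["death_date"]).notna()]
        dead = dead[pd.to_datetime(dead["death_date"]) < pd.Timestamp("2015-06-01")]
        if len(dead):
            take = dead.sample(n=min(k, len(dead)), random_state=int(rng.integers(0, 2**31)), replace=True)
            n_post_death = len(take)
            planted.append(
                pd.DataFrame(
                    {
                        "participant_id": take["participant_id"].to_numpy(),
                        "issue_date": pd.to_datetime(take["death_date"]).to_numpy()
                        + pd.to_timedelta(rng.integers(30, 300, size=n_post_death), unit="D"),
                        "drug_raw": rng.choice(base["generic"], size=n_post_death),
                        "route": "oral",
                        "supplier": take["supplier"].to_numpy(),
                    }
                )
            )
    if planted:
        records = pd.concat([records] + planted, ignore_index=True)

    audit = {
        "n_organic": total,
        "n_empty_name": viol.get("empty_name", 0),
        "n_unmatched_name": viol.get("unmatched_name", 0),
        "n_missing_date": viol.get("missing_date", 0),
        "n_impossible_date": viol.get("impossible_date", 0),
        "n_post_death": n_post_death,
        "n_combination_records": n_combo,
        "combination_surplus": combo_surplus,
    }
    return records.reset_index(drop=True), audit


def simulate_exposure(
    participants: pd.DataFrame,
    truth: SimulationTruth,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct draw of per-participant burden and polypharmacy counts.

    A fast stand-in for the full prescription→cleaning→scoring path used in
    Monte-Carlo studies: burden is zero-inflated and right-skewed (Bernoulli
    gate × gamma), with the same age/comorbidity confounding as
    :func:`simulate_prescriptions`, and the non-anticholinergic prescription
    count is correlated with burden given the covariates so that adjusting
    for polypharmacy attenuates the burden coefficient.
    """
    rng = _rng(seed)
    n = len(participants)
    age_z = _zscore(participants["age"].to_numpy())
    com_z = _zscore(participants["comorbidity_count"].to_numpy())
    a_age = truth.confounder_effects.get("age", (0.0, 0.0))[0]
    a_com = truth.confounder_effects.get("comorbidity_count", (0.0, 0.0))[0]
    eta = a_age * age_z + a_com * com_z
    any_exposure = rng.random(n) < 1 / (1 + np.exp(-(-0.4 + eta)))
    # Confounding acts through the exposure gate; the positive part is
    # right-skewed but bounded, so the 4-SD/4-IQR outlier bounds exceed the
    # support and the planted standardized effect is exactly recoverable.
    positive = 6.0 * rng.beta(1.6, 2.2, size=n)
    achb = np.where(any_exposure, positive, 0.0)
    ac_count = rng.poisson(achb / 1.5)
    n_nonac = rng.poisson(np.exp(2.2 + 0.35 * eta + 0.25 * np.log1p(achb)))
    return pd.DataFrame(
        {
            "participant_id": participants["participant_id"].to_numpy(),
            "achb": achb,
            "ac_count": ac_count,
            "n_nonac": n_nonac,
            "total_rx": ac_count + n_nonac,
            "n_years": rng.integers(3, 16, size=n),
        }
    )


def _residual_cov(loadings: np.ndarray, tests: list[str], pairs: list[tuple[str, str, float]]) -> np.ndarray:
    theta = np.diag(1.0 - loadings**2)
    idx = {t: i for i, t in enumerate(tests)}
    for a, b, rho in pairs:
        if a in idx and b in idx:
            i, j = idx[a], idx[b]
            theta[i, j] = theta[j, i] = rho * np.sqrt(theta[i, i] * theta[j, j])
    return theta


def simulate_cognition(
    participants: pd.DataFrame,
    burden: np.ndarray | pd.Series,
    truth: SimulationTruth,
    battery: list[str] | None = None,
    seed: int = 0,
    polypharmacy: np.ndarray | pd.Series | None = None,
    binary_prevalence: float = 0.85,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a latent-factor cognitive battery with a planted burden effect.

    Latent g is a unit-variance combination of standardized burden
    (coefficient ``truth.beta_achb_g``), the observed confounders, an
    optional direct polypharmacy effect, and noise; each test score is
    ``λ_j·g + e_j`` with the configured residual correlations.  One
    designated test is binary (latent score thresholded at
    *binary_prevalence*); visit-2-only tests are missing for participants
    without an imaging visit.  Returns (wide score table, true g).
    """
    battery = list(battery if battery is not None else truth.loadings)
    if not battery:
        raise ValueError("battery must be nonempty")
    missing_loadings = [t for t in battery if t not in truth.loadings]
    if missing_loadings:
        raise ConfigurationError(f"no loading defined for tests {missing_loadings}")
    rng = _rng(seed)
    n = len(participants)
    achb_z = _zscore(np.asarray(burden, dtype=float))
    lin = truth.beta_achb_g * achb_z
    for cov, (_, eff_g) in truth.confounder_effects.items():
        if cov in participants.columns and eff_g != 0:
            lin = lin + eff_g * _zscore(participants[cov].to_numpy())
    if polypharmacy is not None and truth.beta_polypharmacy_g != 0:
        lin = lin + truth.beta_polypharmacy_g * _zscore(np.asarray(polypharmacy, dtype=float))
    resid_var = max(1.0 - float(np.var(lin)), 0.05)
    g = lin + rng.normal(0.0, np.sqrt(resid_var), size=n)

    lam = np.array([truth.loadings[t] for t in battery])
    theta = _residual_cov(lam, battery, truth.residual_correlations)
    try:
        chol = np.linalg.cholesky(theta)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("residual correlation matrix is not positive definite") from exc
    resid = rng.standard_normal((n, len(battery))) @ chol.T
    scores = g[:, None] * lam[None, :] + resid
    df = pd.DataFrame(scores, columns=battery)
    df.insert(0, "participant_id", participants["participant_id"].to_numpy())
    if BINARY_TEST in battery:
        cut = np.quantile(df[BINARY_TEST], 1 - binary_prevalence)
        df[BINARY_TEST] = (df[BINARY_TEST] > cut).astype(float)
    if "has_imaging" in participants.columns:
        no_img = ~participants["has_imaging"].to_numpy()
        for t in battery:
            if t in VISIT2_ONLY_TESTS:
                df.loc[no_img, t] = np.nan
    return df, pd.Series(g, index=df.index, name="g_true")


def equicorrelation_for_share(share: float, p: int) -> float:
    """Equicorrelation ρ giving a first-PC variance share of *share* for p variables.

    Inverts share = ρ + (1 − ρ)/p.
    """
    return (share - 1.0 / p) / (1.0 - 1.0 / p)


def simulate_imaging(
    participants: pd.DataFrame,
    burden: np.ndarray | pd.Series,
    truth: SimulationTruth,
    n_regions: int = 14,
    n_tracts: int = 25,
    seed: int = 0,
    fa_share: float = 0.44,
    md_share: float = 0.50,
) -> pd.DataFrame:
    """Imaging-derived phenotypes with (by default) null burden effects.

    Regional volumes decline with age and share a global-size factor; a
    T1-based head-size scaling factor column is emitted alongside the raw
    volumes (multiply to correct).  Tract FA/MD come from one-factor
    (equicorrelation) models whose first principal component explains
    *fa_share* / *md_share* of variance in expectation.  A planted burden
    effect ``truth.beta_achb_brain`` (default 0) is added to every outcome
    on the standardized scale.
    """
    if n_regions < 1 or n_tracts < 1:
        raise ValueError("n_regions and n_tracts must be >= 1")
    rng = _rng(seed)
    n = len(participants)
    achb_z = _zscore(np.asarray(burden, dtype=float))
    age_z = _zscore(participants["age"].to_numpy())
    b = truth.beta_achb_brain
    cols: dict[str, np.ndarray] = {"participant_id": participants["participant_id"].to_numpy()}
    scaling = rng.normal(1.0, 0.04, size=n).clip(0.8, 1.2)
    cols["head_scaling"] = scaling
    global_size = rng.standard_normal(n)
    tbv = -0.35 * age_z + 0.7 * global_size + b * achb_z
    tbv = tbv + rng.normal(0, np.sqrt(max(1 - np.var(tbv), 0.05)), size=n)
    cols["total_brain_volume"] = (1500 + 80 * tbv) / scaling  # raw (uncorrected) ml
    for j in range(n_regions):
        v = -0.25 * age_z + 0.5 * global_size + b * achb_z
        v = v + rng.normal(0, np.sqrt(max(1 - np.var(v), 0.05)), size=n)
        cols[f"region_vol_{j + 1:02d}"] = (10 + 1.2 * v) / scaling

    for prefix, share, n_cols in (("tract_fa", fa_share, n_tracts), ("tract_md", md_share, n_tracts)):
        rho = equicorrelation_for_share(share, n_cols) if n_cols > 1 else 1.0
        f = rng.standard_normal(n)
        if n_cols == 1:
            x = f[:, None].copy()
        else:
            x = np.sqrt(rho) * f[:, None] + np.sqrt(1 - rho) * rng.standard_normal((n, n_cols))
        x = x + b * achb_z[:, None]
        for j in range(n_cols):
            cols[f"{prefix}_{j + 1:02d}"] = x[:, j]
    for c in ("head_pos_x", "head_pos_y", "head_pos_z"):
        cols[c] = rng.standard_normal(n)
    return pd.DataFrame(cols)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Fan one master seed out to n independent child seeds (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
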