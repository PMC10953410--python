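"""Latent general cognitive ability (g) and general white-matter factors.

The cognitive battery is summarized by a one-factor confirmatory factor
model: each test score loads on a single latent factor g, with residual
covariances allowed for designated test pairs (tests that share method
variance beyond g).  The model is estimated by maximum likelihood on the
(pairwise-complete) correlation matrix of the indicators,

    Sigma(theta) = lambda lambda' + Theta,

with the factor variance fixed to 1 for identification and Theta diagonal
except at the designated pairs.  Factor scores use the regression method,
``g_hat = lambda' Sigma^{-1} z``, evaluated per participant on the observed
indicator subset (the conditional expectation of g given the non-missing
tests).  The maximal correlation between ``g_hat`` and true g implied by
the model — the factor determinacy — has the closed form
``sqrt(lambda' Sigma^{-1} lambda)`` and serves as an oracle in recovery
tests.

General FA and MD (gFA/gMD) are the first principal components of the
tract-level correlation matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

_PSI_FLOOR = 1e-6
_HEYWOOD_TOL = 1e-4


class ConvergenceError(RuntimeError):
    """Raised when the CFA optimizer fails to converge."""


@dataclass(frozen=True)
class CFASpec:
    """Specification of the one-factor model.

    ``reference_indicator`` is the test whose unstandardized loading is
    reported as fixed to 1; ``sign_indicator`` (default: the reference, else
    the first indicator) pins the direction of the factor so that its
    standardized loading is positive.
    """

    indicators: tuple[str, ...]
    residual_pairs: tuple[tuple[str, str], ...] = ()
    reference_indicator: str | None = None
    sign_indicator: str | None = None

    def __post_init__(self) -> None:
        if len(self.indicators) < 3:
            raise ValueError("a one-factor model needs at least 3 indicators")
        for a, b in self.residual_pairs:
            if a == b:
                raise ValueError(f"residual pair ({a}, {b}) is a self-pair")
            if a not in self.indicators or b not in self.indicators:
                raise ValueError(f"residual pair ({a}, {b}) references unknown indicators")
        if self.reference_indicator is not None and self.reference_indicator not in self.indicators:
            raise ValueError(f"reference indicator {self.reference_indicator!r} not among indicators")


@dataclass
class CFAFit:
    """Fitted one-factor model (standardized solution).

    ``standardized_loadings`` are the loadings on the unit-variance factor
    with unit-variance indicators; ``proportional_variance`` is the mean
    squared standardized loading (share of indicator variance explained by
    g).  ``implied_corr`` is the model-implied indicator correlation matrix
    used for factor scoring.
    """

    spec: CFASpec
    standardized_loadings: pd.Series
    residual_variances: pd.Series
    residual_covariances: dict[tuple[str, str], float]
    proportional_variance: float
    fit_stats: dict[str, float]
    implied_corr: np.ndarray
    sample_corr: np.ndarray
    means: pd.Series
    sds: pd.Series
    n_effective: int
    converged: bool
    heywood: bool
    unstandardized_loadings: pd.Series = field(default=None)  # reference loading = 1

    @property
    def loadings_vector(self) -> np.ndarray:
        return self.standardized_loadings.to_numpy()


def _pairwise_corr(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    """Pairwise-complete correlation matrix, per-column stats and effective n."""
    corr = df.corr(min_periods=2).to_numpy()
    notna = df.notna().to_numpy().astype(float)
    counts = notna.T @ notna
    n_eff = int(np.median(counts))
    return corr, counts, n_eff


def fit_cfa(scores: pd.DataFrame, spec: CFASpec, max_iter: int = 500, gtol: float = 1e-8) -> CFAFit:
    """Fit the one-factor model by maximum likelihood.

    *scores* is a participant × test table (extra columns ignored; missing
    values handled pairwise at the covariance stage).  Raises
    :class:`ConvergenceError` with the gradient norm on failure; a Heywood
    case (residual variance at its lower bound) is flagged, not fatal.
    """
    cols = list(spec.indicators)
    missing_cols = [c for c in cols if c not in scores.columns]
    if missing_cols:
        raise ValueError(f"score table lacks indicator columns {missing_cols}")
    df = scores[cols].astype(float)
    p = len(cols)
    n_rows = int(df.notna().any(axis=1).sum())
    if n_rows < 10 * p:
        raise ValueError(f"need >= {10 * p} participants for {p} indicators, have {n_rows}")
    R, _, n_eff = _pairwise_corr(df)
    if np.isnan(R).any():
        raise ValueError("pairwise-complete correlations undefined for some indicator pair")
    idx = {c: i for i, c in enumerate(cols)}
    pairs = [(idx[a], idx[b]) for a, b in spec.residual_pairs]
    q = len(pairs)

    def unpack(theta: np.ndarray):
        lam = theta[:p]
        psi = np.exp(theta[p : 2 * p])
        c = theta[2 * p :]
        return lam, psi, c

    def implied(theta: np.ndarray) -> np.ndarray:
        lam, psi, c = unpack(theta)
        sigma = np.outer(lam, lam) + np.diag(psi)
        for (i, j), cv in zip(pairs, c):
            sigma[i, j] += cv
            sigma[j, i] += cv
        return sigma

    sign_r, logdet_r = np.linalg.slogdet(R)
    if sign_r <= 0:
        raise ValueError("sample correlation matrix is not positive definite")

    def discrepancy(theta: np.ndarray) -> float:
        sigma = implied(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e10
        return float(logdet + np.trace(np.linalg.solve(sigma, R)) - logdet_r - p)

    x0 = np.concatenate([np.full(p, 0.5), np.full(p, np.log(0.5)), np.zeros(q)])
    bounds = [(None, None)] * p + [(np.log(_PSI_FLOOR), None)] * p + [(None, None)] * q
    res = minimize(
        discrepancy,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": gtol, "maxfun": 100_000},
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    if not res.success and grad_norm > 1e-3:
        raise ConvergenceError(f"CFA did not converge: {res.message} (|grad|_inf = {grad_norm:.2e})")

    lam, psi, c = unpack(res.x)
    heywood = bool((psi < _HEYWOOD_TOL).any())
    if heywood:
        warnings.warn("Heywood case: residual variance bounded at floor", stacklevel=2)
    sigma = implied(res.x)
    sd_implied = np.sqrt(np.diag(sigma))
    lam_std = lam / sd_implied
    # pin the factor direction
    sign_ind = spec.sign_indicator or spec.reference_indicator or cols[0]
    if lam_std[idx[sign_ind]] < 0:
        lam, lam_std = -lam, -lam_std
    ref = spec.reference_indicator or cols[0]
    lam_unstd = lam / lam[idx[ref]] if lam[idx[ref]] != 0 else lam

    # fit statistics against the saturated and independence models
    f_min = max(discrepancy(res.x), 0.0)
    n_params = 2 * p + q
    dof = p * (p + 1) // 2 - n_params
    chi2 = (n_eff - 1) * f_min
    chi2_b = (n_eff - 1) * (-logdet_r)
    dof_b = p * (p - 1) // 2
    cfi = 1.0 - max(chi2 - dof, 0) / max(chi2_b - dof_b, chi2 - dof, 1e-12)
    tli = ((chi2_b / dof_b) - (chi2 / dof)) / max((chi2_b / dof_b) - 1.0, 1e-12) if dof > 0 else np.nan
    rmsea = float(np.sqrt(max(chi2 - dof, 0) / (dof * (n_eff - 1)))) if dof > 0 else np.nan
    srmr = float(np.sqrt(np.mean((R - sigma)[np.triu_indices(p)] ** 2)))
    stats = {
        "chi2": float(chi2),
        "df": float(dof),
        "cfi": float(min(cfi, 1.0)),
        "tli": float(tli),
        "rmsea": rmsea,
        "srmr": srmr,
        "f_min": f_min,
    }
    sigma_std = sigma / np.outer(sd_implied, sd_implied)
    rescov = {(a, b): float(cv / (sd_implied[idx[a]] * sd_implied[idx[b]])) for (a, b), cv in zip(spec.residual_pairs, c)}
    return CFAFit(
        spec=spec,
        standardized_loadings=pd.Series(lam_std, index=cols),
        residual_variances=pd.Series(psi / np.diag(sigma), index=cols),
        residual_covariances=rescov,
        proportional_variance=float(np.mean(lam_std**2)),
        fit_stats=stats,
        implied_corr=sigma_std,
        sample_corr=R,
        means=df.mean(),
        sds=df.std(ddof=1),
        n_effective=n_eff,
        converged=True,
        heywood=heywood,
        unstandardized_loadings=pd.Series(lam_unstd, index=cols),
    )


def factor_determinacy(fit: CFAFit) -> float:
    """Closed-form correlation between regression factor scores and true g."""
    lam = fit.loadings_vector
    return float(np.sqrt(lam @ np.linalg.solve(fit.implied_corr, lam)))


def score_g(fit: CFAFit, scores: pd.DataFrame) -> pd.Series:
    """Regression-method factor scores on the available indicator subset.

    Each participant's score is the conditional expectation of g given their
    observed (standardized) indicators under the fitted model; scores are
    standardized to mean 0, SD 1 over scored participants.  Participants
    with no non-missing indicator get NaN (count in ``result.attrs``).
    """
    cols = list(fit.spec.indicators)
    z = (scores[cols].astype(float) - fit.means) / fit.sds
    zmat = z.to_numpy()
    obs = ~np.isnan(zmat)
    lam = fit.loadings_vector
    sigma = fit.implied_corr
    out = np.full(len(z), np.nan)
    # one linear solve per missingness pattern
    patterns: dict[bytes, np.ndarray] = {}
    keys = [row.tobytes() for row in obs]
    for key in set(keys):
        mask = np.frombuffer(key, dtype=bool)
        if not mask.any():
            continue
        patterns[key] = np.linalg.solve(sigma[np.ix_(mask, mask)], lam[mask])
    for i, key in enumerate(keys):
        w = patterns.get(key)
        if w is None:
            continue
        mask = np.frombuffer(key, dtype=bool)
        out[i] = w @ zmat[i, mask]
    scored = ~np.isnan(out)
    if scored.any():
        out[scored] = (out[scored] - out[scored].mean()) / out[scored].std()
    result = pd.Series(out, index=scores.index, name="g")
    result.attrs["n_unscored"] = int((~scored).sum())
    return result


def prefer_visit(primary: pd.Series, fallback: pd.Series) -> pd.Series:
    """Combine per-visit g scores, preferring the primary (imaging) visit."""
    return primary.where(primary.notna(), fallback)


@dataclass
class GeneralPCResult:
    """First principal component of a tract table: gFA or gMD."""

    loadings: pd.Series
    variance_share: float
    scores: pd.Series
    dropped_columns: tuple[str, ...] = ()


def fit_general_pc(tract_table: pd.DataFrame, measure: str | None = None) -> GeneralPCResult:
    """First principal component of the tract correlation matrix.

    Columns are standardized, so the variance share is
    ``lambda_1 / p``; the component sign is fixed so the mean loading is
    positive, and scores are standardized.  Constant columns are dropped
    with a warning.  *measure* optionally selects columns by prefix (e.g.
    ``"tract_fa"``).
    """
    df = tract_table.select_dtypes(include=[np.number]).copy()
    if measure is not None:
        df = df[[c for c in df.columns if c.startswith(measure)]]
    df = df.dropna()
    sds = df.std(ddof=1)
    constant = tuple(sds.index[(sds == 0) | sds.isna()])
    if constant:
        warnings.warn(f"dropping constant tract column(s): {list(constant)}", stacklevel=2)
        df = df.drop(columns=list(constant))
    if df.shape[1] == 0:
        raise ValueError("no usable tract columns")
    if df.shape[1] == 1:
        col = df.columns[0]
        z = (df[col] - df[col].mean()) / df[col].std(ddof=1)
        return GeneralPCResult(
            loadings=pd.Series([1.0], index=[col]),
            variance_share=1.0,
            scores=z.rename("general_pc"),
            dropped_columns=constant,
        )
    z = (df - df.mean()) / df.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    lam1 = float(evals[-1])
    v = evecs[:, -1]
    if v.mean() < 0:
        v = -v
    loadings = pd.Series(v * np.sqrt(lam1), index=df.columns)
    raw = z.to_numpy() @ v
    scores = pd.Series((raw - raw.mean()) / raw.std(ddof=1), index=df.index, name="general_pc")
    return GeneralPCResult(
        loadings=loadings,
        variance_share=lam1 / df.shape[1],
        scores=scores,
        dropped_columns=constant,
    )
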