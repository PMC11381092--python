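"""Biomarker change scores, assay QC and the model-selection layer.

Foraging success is scored as the log-ratio change of mass and plasma
biomarkers over a deployment, delta = log(post) - log(pre) (natural log).
Candidate linear (mixed) models for each behavioural or physiological
response are screened for collinearity (VIF > 5 for single-df terms,
GVIF^(1/2df) > 2.2 for multi-df terms, interactions removed before main
effects), fitted by maximum likelihood, ranked by AICc, the top model is
compared to the null by a likelihood-ratio test, refitted by REML for
coefficient t-statistics, and summarized with marginal and conditional R2
(fixed-effect vs fixed-plus-random variance shares).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

ANALYTES = ("MASS", "TRIG", "BCORT", "BOH", "NEFA")


@dataclass
class BiomarkerPanel:
    bird_id: str
    analyte: str
    pre: float
    post: float
    time_at_colony_h: float = np.nan

    def __post_init__(self):
        if self.pre <= 0 or self.post <= 0:
            raise ValueError("analyte values must be positive")

    @property
    def delta(self) -> float:
        return delta(self.pre, self.post)


def delta(pre: float, post: float) -> float:
    """Relative change: log(post) - log(pre); antisymmetric under swap."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(pre <= 0) or np.any(post <= 0):
        raise ValueError("pre/post must be strictly positive")
    return np.log(post) - np.log(pre)


def assay_cv(replicates: dict) -> tuple[float, float]:
    """Intra- and inter-assay coefficients of variation (percent).

    ``replicates`` maps plate id -> control replicate values.  Intra-assay
    CV is the mean over plates of 100*SD/mean of within-plate replicates;
    inter-assay CV is 100*SD/mean of the plate means.  Sample SD (ddof=1).
    """
    plate_cvs, plate_means = [], []
    for plate, vals in replicates.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            warnings.warn(f"plate {plate}: single replicate, skipped for intra-assay CV")
        else:
            plate_cvs.append(100.0 * vals.std(ddof=1) / vals.mean())
        plate_means.append(vals.mean())
    intra = float(np.mean(plate_cvs)) if plate_cvs else float("nan")
    if len(plate_means) < 2:
        warnings.warn("single plate: inter-assay CV unavailable")
        inter = float("nan")
    else:
        pm = np.asarray(plate_means)
        inter = float(100.0 * pm.std(ddof=1) / pm.mean())
    return intra, inter


# ---------------------------------------------------------------------------
# collinearity screening

def _gvif(R: np.ndarray, cols_in_term: np.ndarray) -> float:
    """Fox-Monette generalized VIF from the predictor correlation matrix."""
    other = ~cols_in_term
    det = np.linalg.det
    d = det(R)
    if d <= 1e-300:
        return np.inf
    return det(R[np.ix_(cols_in_term, cols_in_term)]) * det(R[np.ix_(other, other)]) / d


def vif_screen(design: pd.DataFrame, terms: dict[str, list[str]] | None = None,
               vif_thr: float = 5.0, gvif_thr: float = 2.2):
    """Iteratively drop collinear terms from a numeric design table.

    ``terms`` maps a term name to its design columns (default: one term per
    column); a term whose name contains ':' is treated as an interaction
    and removed before main effects.  Single-df terms are judged by
    VIF = 1/(1-R2) > vif_thr, multi-df terms by GVIF^(1/(2 df)) > gvif_thr,
    worst offender first.  Returns (retained term names, report DataFrame).
    """
    if terms is None:
        terms = {c: [c] for c in design.columns}
    terms = {k: list(v) for k, v in terms.items()}
    report = []
    while True:
        names = list(terms)
        cols = [c for n in names for c in terms[n]]
        if len(names) < 2:
            break
        X = design[cols].to_numpy(dtype=float)
        R = np.corrcoef(X, rowvar=False)
        offenders = []
        for n in names:
            in_term = np.array([c in terms[n] for c in cols])
            df_term = int(in_term.sum())
            g = _gvif(R, in_term)
            if df_term == 1:
                value, thr, kind = g, vif_thr, "VIF"
            else:
                value, thr, kind = g ** (1.0 / (2 * df_term)), gvif_thr, "GVIF^(1/2df)"
            report.append({"term": n, "metric": kind, "value": value,
                           "threshold": thr, "n_terms": len(names)})
            if value > thr:
                offenders.append((":" in n, value, n))
        if not offenders:
            break
        offenders.sort(key=lambda o: (o[0], o[1]), reverse=True)
        drop = offenders[0][2]
        del terms[drop]
        report.append({"term": drop, "metric": "removed", "value": np.nan,
                       "threshold": np.nan, "n_terms": len(terms)})
    return list(terms), pd.DataFrame(report)


# ---------------------------------------------------------------------------
# information-theoretic model ranking

def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n-k-1); undefined unless n > k+1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class ModelRow:
    formula: str
    k: int
    n: int
    loglik: float
    aicc: float
    delta_aicc: float = np.nan
    weight: float = np.nan
    r2_marginal: float = np.nan
    r2_conditional: float = np.nan
    random_effect: str = "NONE"
    fit: object = field(default=None, repr=False, compare=False)


def _k_params(fit, random_effect: str) -> int:
    p = len(fit.fe_params) if hasattr(fit, "fe_params") else len(fit.params)
    k = p + 1                                   # + residual variance
    if random_effect == "BIRD_ID" and hasattr(fit, "fe_params"):
        k += 1                                  # + random-intercept variance
    return k


def _fit_one(data: pd.DataFrame, response: str, rhs: str, random_effect: str,
             reml: bool = False):
    formula = f"{response} ~ {rhs}"
    if random_effect == "BIRD_ID":
        model = smf.mixedlm(formula, data, groups=data["bird_id"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return model.fit(reml=reml)
            except np.linalg.LinAlgError:
                return model.fit(reml=reml, method="powell")
    return smf.ols(formula, data).fit()


def fit_candidates(data: pd.DataFrame, response: str, candidates: list[str],
                   random_effect: str = "NONE") -> list[ModelRow]:
    """ML-fit each candidate fixed-effect structure and rank by AICc.

    ``candidates`` are model right-hand sides (patsy formulas); the set
    should include the null (intercept + mandatory covariates) model.
    Candidates with more parameters than rows are skipped with a warning.
    Returns rows sorted by AICc with delta-AICc and Akaike weights filled.
    """
    rows = []
    sub = data.dropna(subset=[response]).copy()
    n = len(sub)
    for rhs in candidates:
        try:
            fit = _fit_one(sub, response, rhs, random_effect, reml=False)
            k = _k_params(fit, random_effect)
            if n <= k + 1:
                raise ValueError("too few rows for AICc")
            r2m, r2c = r2_nakagawa(fit)
            rows.append(ModelRow(formula=rhs, k=k, n=n, loglik=float(fit.llf),
                                 aicc=aicc(float(fit.llf), k, n),
                                 r2_marginal=r2m, r2_conditional=r2c,
                                 random_effect=random_effect, fit=fit))
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"candidate {rhs!r} skipped: {exc}")
    if not rows:
        raise ValueError("no candidate model could be fitted")
    rows.sort(key=lambda r: r.aicc)
    best = rows[0].aicc
    for r in rows:
        r.delta_aicc = r.aicc - best
    w = np.exp(-0.5 * np.array([r.delta_aicc for r in rows]))
    w /= w.sum()
    for r, wi in zip(rows, w):
        r.weight = float(wi)
    return rows


def model_table(rows: list[ModelRow]) -> pd.DataFrame:
    return pd.DataFrame([{k: v for k, v in vars(r).items() if k != "fit"}
                         for r in rows])


def compare_to_null(top: ModelRow, null: ModelRow) -> tuple[float, int, float]:
    """Likelihood-ratio test of the top model against the nested null."""
    top_terms = set(top.fit.model.exog_names)
    null_terms = set(null.fit.model.exog_names)
    if not null_terms <= top_terms:
        raise ValueError("null model is not nested in the top model")
    stat = 2.0 * (top.loglik - null.loglik)
    if stat < 0:
        warnings.warn("negative LR statistic clipped to 0")
        stat = 0.0
    df = top.k - null.k
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def r2_nakagawa(fit) -> tuple[float, float]:
    """Marginal and conditional R2 for a Gaussian (mixed) model.

    r2m = var_f / (var_f + var_r + var_e), r2c adds var_r to the numerator;
    var_f is the sample variance of the fixed-effect predictions.
    """
    if hasattr(fit, "fe_params"):       # MixedLM
        X = fit.model.exog
        pred = X @ fit.fe_params
        var_f = float(np.var(pred, ddof=1)) if len(pred) > 1 else 0.0
        var_r = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
        var_e = float(fit.scale)
    else:                               # OLS
        pred = fit.fittedvalues
        var_f = float(np.var(pred, ddof=1)) if len(pred) > 1 else 0.0
        var_r = 0.0
        var_e = float(fit.scale)
    denom = var_f + var_r + var_e
    if denom <= 0:
        return 0.0, 0.0
    return var_f / denom, (var_f + var_r) / denom


@dataclass
class ReMLFit:
    coefficients: pd.DataFrame     # term, estimate, se, t, df, p
    random_intercept_sd: float
    residual_sd: float
    singular: bool
    fit: object = field(repr=False, default=None)


def refit_reml(data: pd.DataFrame, response: str, rhs: str,
               random_effect: str = "NONE") -> ReMLFit:
    """REML refit of a selected model with coefficient t-statistics.

    Denominator df uses the residual approximation n - p.  A singular mixed
    fit (random-intercept variance at the boundary) is refitted as an
    ordinary linear model and flagged.
    """
    sub = data.dropna(subset=[response]).copy()
    singular = False
    if random_effect == "BIRD_ID":
        fit = _fit_one(sub, response, rhs, "BIRD_ID", reml=True)
        re_var = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
        if re_var < 1e-8:
            singular = True
            fit = _fit_one(sub, response, rhs, "NONE")
            re_var = 0.0
    else:
        fit = _fit_one(sub, response, rhs, "NONE")
        re_var = 0.0
    if hasattr(fit, "fe_params"):
        params, bse = fit.fe_params, fit.bse_fe
        p = len(params)
    else:
        params, bse = fit.params, fit.bse
        p = len(params)
    df = len(sub) - p
    t = params / bse
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    coefs = pd.DataFrame({"term": list(params.index), "estimate": params.values,
                          "se": bse.values, "t": np.asarray(t),
                          "df": df, "p": pvals})
    return ReMLFit(coefficients=coefs, random_intercept_sd=float(np.sqrt(re_var)),
                   residual_sd=float(np.sqrt(fit.scale)), singular=singular, fit=fit)
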