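"""Longitudinal and correlational statistics for the biomarker analysis.

Implements the study's statistical layer on plasma biomarker samples
(Aβ40, Aβ42, their ratio, P-Tau181, GFAP, NfL):

* per-subject overnight change (mean Day-2 minus mean Day-1 concentration);
* linear mixed models with a subject-specific random intercept, fitted by
  maximum likelihood, optionally with distinct residual variances per
  follow-up day (chosen by a likelihood-ratio test at alpha = 0.05 unless
  forced);
* the Day-2 group comparison adjusted for Day-1 group means (constrained
  baseline: groups share the Day-1 mean, the contrast is the group
  difference in day-to-day change);
* the group x day interaction model;
* degree-one fractional polynomial (FP1) regression of concentration on
  clock time with cluster-robust (sandwich) standard errors over repeated
  draws of the same subject;
* Pearson correlation panels per intervention group.

All p-values are two-tailed and unadjusted for multiplicity, matching the
reporting convention of the source analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
import statsmodels.api as sm

logger = logging.getLogger("csfclear.stats")

__all__ = [
    "BIOMARKERS",
    "FP1_POWERS",
    "LMMResult",
    "FP1Result",
    "CorrelationResult",
    "RankDeficientError",
    "overnight_change",
    "fit_random_intercept_lmm",
    "day2_group_comparison",
    "group_day_interaction",
    "fp1_regression",
    "pearson_panel",
    "ab_ratio",
]

BIOMARKERS = ("AB40", "AB42", "AB42_AB40_RATIO", "PTAU181", "GFAP", "NFL")

#: candidate exponents of the degree-one fractional polynomial; 0 denotes ln x
FP1_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


class RankDeficientError(ValueError):
    """The fixed-effects design matrix is rank deficient."""


@dataclass
class LMMResult:
    fixed_effects: dict  # name -> (estimate, SE, p)
    random_intercept_var: float
    residual_var: dict  # stratum label -> variance
    loglik: float
    n_obs: int
    n_subjects: int
    converged: bool
    contrast_name: str | None = None

    def contrast(self):
        """(estimate, SE, p) of the designated contrast, if any."""
        if self.contrast_name is None:
            raise ValueError("model has no designated contrast")
        return self.fixed_effects[self.contrast_name]


@dataclass
class FP1Result:
    power: float
    coefficients: dict  # {"intercept": ..., "slope": ...}
    robust_se: dict
    p_values: dict
    loglik: float
    shift: float
    prediction: pd.DataFrame  # columns time, mean, lo95, hi95


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    slope: float
    intercept: float


# --------------------------------------------------------------------------
# overnight change
# --------------------------------------------------------------------------

def overnight_change(samples: pd.DataFrame) -> pd.DataFrame:
    """Mean Day-2 minus mean Day-1 concentration per subject x biomarker.

    ``samples`` has columns subject_id, biomarker, day, conc (extra columns
    ignored).  Subject/biomarker combinations missing either day are omitted
    with a warning, not an error.
    """
    means = (samples.groupby(["subject_id", "biomarker", "day"])["conc"]
             .mean().unstack("day"))
    missing = means[means.isna().any(axis=1)]
    for sid, marker in missing.index:
        logger.warning("overnight change for %s/%s skipped: a day is missing",
                       sid, marker)
    both = means.dropna()
    out = (both[2] - both[1]).rename("delta").reset_index()
    return out


def ab_ratio(ab42_conc, ab40_conc):
    """Elementwise Aβ42/Aβ40 ratio; zero Aβ40 is an error."""
    a42 = np.asarray(ab42_conc, float)
    a40 = np.asarray(ab40_conc, float)
    if np.any(a40 == 0):
        raise ValueError("Aβ40 concentration of zero: ratio undefined")
    out = a42 / a40
    if np.isscalar(ab42_conc) and np.isscalar(ab40_conc):
        return float(out)
    return out


# --------------------------------------------------------------------------
# random-intercept linear mixed model (profiled ML)
# --------------------------------------------------------------------------

def _encode_terms(data: pd.DataFrame, terms) -> tuple:
    """Design matrix for main effects and ':' interactions of named columns."""
    def columns_for(name):
        col = data[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(col.astype(str)))
            if len(levels) < 2:
                raise RankDeficientError(
                    f"term {name!r} is constant (single level "
                    f"{levels[0]!r}), collinear with the intercept")
            return [(f"{name}[{lv}]", (col.astype(str) == lv).to_numpy(float))
                    for lv in levels[1:]]  # first level is the reference
        return [(name, col.to_numpy(float))]

    names = ["Intercept"]
    cols = [np.ones(len(data))]
    for term in terms:
        parts = term.split(":")
        pieces = [columns_for(p.strip()) for p in parts]
        combos = pieces[0]
        for nxt in pieces[1:]:
            combos = [(f"{n1}:{n2}", c1 * c2) for n1, c1 in combos
                      for n2, c2 in nxt]
        for n, c in combos:
            names.append(n)
            cols.append(c)
    X = np.column_stack(cols)
    return names, X


def _check_rank(names, X):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1])
               if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise RankDeficientError(
            "design matrix is rank deficient; collinear terms: "
            + ", ".join(bad or names))


def _ml_profile_m2ll(var_logs, y, X, group_idx, strat_idx, n_strata):
    """-2 profiled log-likelihood and GLS quantities for given variances."""
    tau2 = math.exp(var_logs[0])
    sig2 = np.exp(var_logs[1: 1 + n_strata])
    d = sig2[strat_idx]  # per-observation residual variance
    XtVX = np.zeros((X.shape[1], X.shape[1]))
    XtVy = np.zeros(X.shape[1])
    logdet = 0.0
    quad_parts = []
    for rows in group_idx:
        Xi = X[rows]
        yi = y[rows]
        di = d[rows]
        dinv = 1.0 / di
        s = float(np.sum(dinv))
        c = tau2 / (1.0 + tau2 * s)
        # V^-1 = D^-1 - c (D^-1 1)(D^-1 1)'
        Xw = Xi * dinv[:, None]
        yw = yi * dinv
        xs = Xw.sum(axis=0)
        ys = yw.sum()
        XtVX += Xi.T @ Xw - c * np.outer(xs, xs)
        XtVy += Xi.T @ yw - c * xs * ys
        logdet += float(np.sum(np.log(di))) + math.log1p(tau2 * s)
        quad_parts.append((yi, Xi, dinv, c))
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return 1e12, None, None
    quad = 0.0
    for yi, Xi, dinv, c in quad_parts:
        ri = yi - Xi @ beta
        rw = ri * dinv
        quad += float(ri @ rw) - c * float(rw.sum()) ** 2
    n = len(y)
    m2ll = n * math.log(2.0 * math.pi) + logdet + quad
    return m2ll, beta, XtVX


def _fit_ml(y, X, groups, strata=None):
    """Profiled-ML random-intercept fit; returns a parameter dictionary."""
    subj, subj_codes = np.unique(groups, return_inverse=True)
    group_idx = [np.nonzero(subj_codes == k)[0] for k in range(len(subj))]
    if strata is None:
        strat_labels = np.array(["all"])
        strat_idx = np.zeros(len(y), dtype=int)
    else:
        strat_labels, strat_idx = np.unique(np.asarray(strata), return_inverse=True)
    n_strata = len(strat_labels)

    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    v0 = max(float(np.var(resid)), 1e-10)
    x0 = np.log(np.r_[0.5 * v0, np.full(n_strata, 0.5 * v0)])

    def obj(v):
        return _ml_profile_m2ll(v, y, X, group_idx, strat_idx, n_strata)[0]

    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9,
                                     "maxiter": 2000, "maxfev": 2000})
    m2ll, beta, XtVX = _ml_profile_m2ll(res.x, y, X, group_idx, strat_idx,
                                        n_strata)
    cov = np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    return {
        "beta": beta, "se": se, "p": p, "cov": cov,
        "tau2": math.exp(res.x[0]),
        "sigma2": dict(zip([str(s) for s in strat_labels],
                           np.exp(res.x[1:1 + n_strata]))),
        "loglik": -0.5 * m2ll,
        "n_subjects": len(subj),
        "converged": bool(res.success),
    }


def fit_random_intercept_lmm(data: pd.DataFrame, outcome: str, fixed_terms,
                             groups: str = "subject_id",
                             heteroscedastic_by: str | None = "auto",
                             contrast_name: str | None = None) -> LMMResult:
    """ML linear mixed model with a subject-specific random intercept.

    ``fixed_terms`` are column names, with ':' denoting interactions
    (categorical columns are dummy-coded against their first level).  When
    ``heteroscedastic_by`` names a column, residual variance is estimated per
    level of that column; ``"auto"`` stratifies by ``day`` (when present) only
    if a likelihood-ratio test at alpha = 0.05 favours it; ``None`` forces a
    single residual variance.  Wald z p-values are two-tailed.
    """
    data = data.reset_index(drop=True)
    y = data[outcome].to_numpy(float)
    if len(y) < 2:
        raise ValueError("need at least two observations")
    names, X = _encode_terms(data, fixed_terms)
    _check_rank(names, X)
    g = data[groups].to_numpy()
    if len(np.unique(g)) < 2:
        raise ValueError("need at least two subjects")

    strat_col = None
    if heteroscedastic_by == "auto":
        strat_col = "day" if "day" in data.columns else None
    elif heteroscedastic_by is not None:
        strat_col = heteroscedastic_by

    homo = _fit_ml(y, X, g, strata=None)
    chosen, strata_used = homo, None
    if strat_col is not None and data[strat_col].nunique() > 1:
        het = _fit_ml(y, X, g, strata=data[strat_col].to_numpy())
        if heteroscedastic_by == "auto":
            lrt = 2.0 * (het["loglik"] - homo["loglik"])
            df = data[strat_col].nunique() - 1
            if lrt > sps.chi2.ppf(0.95, df):
                chosen, strata_used = het, strat_col
        else:
            chosen, strata_used = het, strat_col

    fixed = {nm: (float(b), float(s), float(pv))
             for nm, b, s, pv in zip(names, chosen["beta"], chosen["se"],
                                     chosen["p"])}
    return LMMResult(
        fixed_effects=fixed,
        random_intercept_var=float(chosen["tau2"]),
        residual_var={k: float(v) for k, v in chosen["sigma2"].items()},
        loglik=float(chosen["loglik"]),
        n_obs=len(y),
        n_subjects=int(chosen["n_subjects"]),
        converged=bool(chosen["converged"]),
        contrast_name=contrast_name,
    )


def _require_groups_days(data):
    tab = data.groupby(["group", "day"]).size().unstack(fill_value=0)
    if tab.shape[0] < 2:
        raise ValueError("need both intervention groups in the data")
    if (tab == 0).any().any() or tab.shape[1] < 2:
        raise ValueError("each group needs observations on both days")


def day2_group_comparison(data: pd.DataFrame, outcome: str = "conc",
                          heteroscedastic_by: str | None = "auto") -> LMMResult:
    """Day-2 group contrast with Day-1 group means equated.

    Constrained-baseline model: a common Day-1 mean for both groups, a day
    effect, and a group-specific additional day effect whose coefficient is
    the adjusted Day-2 group difference (the designated contrast).
    """
    _require_groups_days(data)
    d = data.copy().reset_index(drop=True)
    d["day2"] = (d["day"].astype(int) == 2).astype(float)
    levels = sorted(d["group"].astype(str).unique())
    d["day2_x_group"] = d["day2"] * (d["group"].astype(str) == levels[1])
    return fit_random_intercept_lmm(
        d, outcome, ["day2", "day2_x_group"],
        heteroscedastic_by=heteroscedastic_by,
        contrast_name="day2_x_group")


def group_day_interaction(data: pd.DataFrame, outcome: str = "conc",
                          heteroscedastic_by: str | None = "auto") -> LMMResult:
    """Full group x day model; the interaction term is the contrast."""
    _require_groups_days(data)
    d = data.copy().reset_index(drop=True)
    d["day"] = d["day"].astype(int).astype(str)
    d["group"] = d["group"].astype(str)
    res = fit_random_intercept_lmm(
        d, outcome, ["group", "day", "group:day"],
        heteroscedastic_by=heteroscedastic_by)
    res.contrast_name = [nm for nm in res.fixed_effects if ":" in nm][0]
    return res


# --------------------------------------------------------------------------
# FP1 regression with cluster-robust errors
# --------------------------------------------------------------------------

def _fp1_transform(x, power):
    return np.log(x) if power == 0 else x ** power


def fp1_regression(time_of_day, conc, cluster_id, n_pred: int = 100) -> FP1Result:
    """Degree-one fractional polynomial fit of concentration on clock time.

    For each power p in {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (p = 0 meaning ln x)
    an ordinary linear model on the transformed time is fitted; the power
    with the highest likelihood wins.  Standard errors are cluster-robust
    (sandwich) over ``cluster_id`` because draws of the same subject are
    correlated.  A positive shift is applied automatically when times are
    not strictly positive.  Returns the fit and a 95% prediction band.
    """
    t = np.asarray(time_of_day, float)
    y = np.asarray(conc, float)
    cid = np.asarray(cluster_id)
    if len(t) < 10:
        raise ValueError("need at least 10 observations")
    shift = 0.0
    if np.min(t) <= 0:
        pos = np.diff(np.unique(t))
        shift = -float(np.min(t)) + (float(np.min(pos)) if len(pos) else 1.0)
    ts = t + shift
    if np.min(ts) <= 0:
        raise ValueError("times remain non-positive after shift")

    best = None
    for power in FP1_POWERS:
        X = sm.add_constant(_fp1_transform(ts, power))
        fit = sm.OLS(y, X).fit(cov_type="cluster",
                               cov_kwds={"groups": cid}, use_t=False)
        if best is None or fit.llf > best[1].llf:
            best = (power, fit)
    power, fit = best

    grid = np.linspace(np.min(t), np.max(t), n_pred)
    Xg = sm.add_constant(_fp1_transform(grid + shift, power), has_constant="add")
    mean = Xg @ fit.params
    var = np.einsum("ij,jk,ik->i", Xg, fit.cov_params(), Xg)
    half = 1.959963984540054 * np.sqrt(np.maximum(var, 0.0))
    pred = pd.DataFrame({"time": grid, "mean": mean,
                         "lo95": mean - half, "hi95": mean + half})
    se = fit.bse
    pv = fit.pvalues
    return FP1Result(
        power=power,
        coefficients={"intercept": float(fit.params[0]),
                      "slope": float(fit.params[1])},
        robust_se={"intercept": float(se[0]), "slope": float(se[1])},
        p_values={"intercept": float(pv[0]), "slope": float(pv[1])},
        loglik=float(fit.llf),
        shift=shift,
        prediction=pred,
    )


# --------------------------------------------------------------------------
# Pearson correlation panels
# --------------------------------------------------------------------------

def pearson_panel(x_index, y_change, group_labels) -> dict:
    """Pearson r, two-tailed p and fit line per intervention group.

    One point per subject; p-values are t-based with n-2 degrees of freedom.
    Zero variance in either variable is an error (correlation undefined).
    """
    x = np.asarray(x_index, float)
    y = np.asarray(y_change, float)
    g = np.asarray(group_labels)
    out = {}
    for label in sorted(pd.unique(g).astype(str)):
        sel = g.astype(str) == label
        xs, ys = x[sel], y[sel]
        keep = np.isfinite(xs) & np.isfinite(ys)
        xs, ys = xs[keep], ys[keep]
        if len(xs) < 3:
            raise ValueError(f"group {label!r}: need n >= 3 finite pairs")
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            raise ValueError(f"group {label!r}: zero variance, "
                             "correlation undefined")
        r, p = sps.pearsonr(xs, ys)
        slope, intercept = np.polyfit(xs, ys, 1)
        out[label] = CorrelationResult(r=float(r), p=float(p), n=len(xs),
                                       slope=float(slope),
                                       intercept=float(intercept))
    return out
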