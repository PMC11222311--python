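"""Descriptive statistics and nested logistic-regression association models.

Implements the cohort-comparison table (median/IQR with Mann-Whitney for
continuous variables; counts/percentages with Pearson chi-square for
categorical ones), univariate covariate screening, the five-model nested
adjustment ladder used to relate each glycemic exposure to postoperative
delirium, and the per-stratum subgroup engine.

Logistic models are fitted by maximum likelihood (IRLS via statsmodels
GLM/Binomial); odds ratios carry Wald 95% CIs ``exp(beta +/- 1.96 SE)``,
which reproduces the printed CI arithmetic on 2x2 tables exactly.
Chi-square is Pearson's statistic without continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

Z_95 = 1.96

#: Nested adjustment sets (records-table column names) for Models 1-5.
MODEL_ADJUSTMENTS: dict[int, tuple] = {
    1: (),
    2: ("age", "hr", "spo2"),
    3: ("age", "hr", "spo2", "rdw", "hematocrit", "egfr", "inr", "pt", "bun",
        "bicarbonate", "na"),
    4: ("age", "hr", "spo2", "rdw", "hematocrit", "egfr", "inr", "pt", "bun",
        "bicarbonate", "na", "sofa", "cci"),
    5: ("age", "hr", "spo2", "rdw", "hematocrit", "egfr", "inr", "pt", "bun",
        "bicarbonate", "na", "sofa", "cci", "sepsis", "ckd", "mech_vent",
        "vasopressor"),
}

#: Exposure column -> (kind, reference level) for the model ladder.
EXPOSURES = {
    "baseline_stratum": ("hyperglycemia", "no"),
    "mbg_stratum": ("hyperglycemia", "no"),
    "mag_high": ("binary", False),
    "mage_high": ("binary", False),
    "gli_high": ("binary", False),
    "lage_high": ("binary", False),
    "trajectory_class": ("class", 1),
}

#: Subgroup variables -> (column, cutpoint or None for binary flags).
SUBGROUP_DEFS = {
    "age": ("age", 65.0),
    "gender": ("gender", None),
    "race": ("race", None),
    "egfr": ("egfr", 60.0),
    "inr": ("inr", 1.5),
    "sepsis": ("sepsis", None),
    "vent": ("mech_vent", None),
    "vasopressor": ("vasopressor", None),
}


class SeparationError(RuntimeError):
    """Complete or quasi-separation in a logistic fit."""


@dataclass
class LogisticFit:
    """One fitted logistic model: log-odds, Wald inference, odds ratios."""

    terms: list
    coefficients: np.ndarray
    covariance: np.ndarray
    n_obs: int
    log_likelihood: float
    converged: bool
    table: pd.DataFrame = field(repr=False, default=None)

    def or_row(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _check_full_rank(X: pd.DataFrame):
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        # name the offending columns by greedy elimination
        cols, keep = list(X.columns), []
        for c in cols:
            trial = keep + [c]
            if np.linalg.matrix_rank(X[trial].to_numpy(dtype=float)) == len(trial):
                keep.append(c)
        dropped = [c for c in cols if c not in keep]
        raise ValueError(f"design is rank deficient; collinear terms: {dropped}")


def fit_logistic(outcome, design: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    ``design`` should NOT contain a constant; one is added. Raises
    :class:`SeparationError` when slope coefficients diverge (max |slope|
    > 15) or the outcome is constant, and ``ValueError`` on a
    rank-deficient design, naming the collinear terms.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError("outcome has no events or no non-events")
    X = sm.add_constant(design.astype(float), has_constant="add")
    _check_full_rank(X)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=100, tol=1e-8)
        except PerfectSeparationError as exc:
            raise SeparationError(f"separation: {exc}") from exc
    beta = res.params.to_numpy()
    slopes = beta[[t != "const" for t in X.columns]]
    if slopes.size and np.max(np.abs(slopes)) > 15:
        # the intercept is exempt: it legitimately grows with unscaled
        # covariate means (e.g. sodium ~ 135 mEq/L)
        raise SeparationError(
            "separation: coefficient magnitude exceeds 15 "
            f"(max |slope| = {np.max(np.abs(slopes)):.1f})")
    se = np.sqrt(np.diag(res.cov_params().to_numpy()))
    terms = list(X.columns)
    with np.errstate(over="ignore"):
        table = pd.DataFrame({
            "coef": beta,
            "se": se,
            "or": np.exp(beta),
            "ci_low": np.exp(beta - Z_95 * se),
            "ci_high": np.exp(beta + Z_95 * se),
            "p": 2 * st.norm.sf(np.abs(beta / se)),
        }, index=terms)
    return LogisticFit(terms=terms, coefficients=beta,
                       covariance=res.cov_params().to_numpy(),
                       n_obs=int(y.size), log_likelihood=float(res.llf),
                       converged=bool(res.converged), table=table)


def chisq_test(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (stat, df, p)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    stat, p, dof, _ = st.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def mann_whitney(x_nonevent, x_event) -> tuple[float, float]:
    """Tie-corrected, continuity-corrected normal-approximation
    Mann-Whitney test; returns (Z, p).

    Z is signed so that an event group with stochastically larger values
    gives a negative Z (the convention used in cohort-comparison tables:
    the non-event group is listed first).
    """
    x0 = np.asarray(x_nonevent, dtype=float)
    x1 = np.asarray(x_event, dtype=float)
    x0, x1 = x0[~np.isnan(x0)], x1[~np.isnan(x1)]
    n0, n1 = x0.size, x1.size
    allv = np.concatenate([x0, x1])
    ranks = st.rankdata(allv)
    u0 = ranks[:n0].sum() - n0 * (n0 + 1) / 2          # U for the non-event group
    mu = n0 * n1 / 2
    # tie-corrected variance
    _, counts = np.unique(allv, return_counts=True)
    n = n0 + n1
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n0 * n1 / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 0.0, 1.0
    diff = u0 - mu
    cc = 0.5 if diff != 0 else 0.0
    z = (diff - np.sign(diff) * cc) / np.sqrt(sigma2)
    return float(z), float(2 * st.norm.sf(abs(z)))


def describe_cohort(records: pd.DataFrame, group_var: str = "pod",
                    continuous=(), categorical=()) -> pd.DataFrame:
    """Cohort-comparison table between the two levels of ``group_var``.

    Continuous variables: median (Q1, Q3) per group plus Mann-Whitney Z/p.
    Categorical: counts (%) per level plus Pearson chi-square (no
    continuity correction). All-missing variables are skipped with a
    warning.
    """
    g = records[group_var]
    if set(g.dropna().unique()) - {0, 1}:
        raise ValueError(f"{group_var} must be binary 0/1")
    g0, g1 = records[g == 0], records[g == 1]
    rows = []
    for var in continuous:
        x0, x1 = g0[var], g1[var]
        if x0.dropna().empty and x1.dropna().empty:
            warnings.warn(f"variable {var!r} is all-missing; skipped")
            continue
        z, p = mann_whitney(x0, x1)
        rows.append({
            "variable": var, "type": "continuous", "level": "",
            "group0": f"{x0.median():.2f} ({x0.quantile(.25):.2f}, "
                      f"{x0.quantile(.75):.2f})",
            "group1": f"{x1.median():.2f} ({x1.quantile(.25):.2f}, "
                      f"{x1.quantile(.75):.2f})",
            "statistic": z, "stat_name": "Z", "df": np.nan, "p": p,
        })
    for var in categorical:
        if records[var].dropna().empty:
            warnings.warn(f"variable {var!r} is all-missing; skipped")
            continue
        ct = pd.crosstab(records[var], g)
        stat, dof, p = chisq_test(ct.to_numpy().T)
        for level in ct.index:
            c0, c1 = ct.loc[level, 0], ct.loc[level, 1]
            rows.append({
                "variable": var, "type": "categorical", "level": str(level),
                "group0": f"{c0} ({100 * c0 / len(g0):.2f})",
                "group1": f"{c1} ({100 * c1 / len(g1):.2f})",
                "statistic": stat, "stat_name": "chi2", "df": dof, "p": p,
            })
    return pd.DataFrame(rows)


def _exposure_design(records: pd.DataFrame, exposure: str) -> pd.DataFrame:
    """Dummy-code an exposure against its declared reference level."""
    if exposure not in EXPOSURES:
        raise ValueError(f"unknown exposure {exposure!r}")
    kind, ref = EXPOSURES[exposure]
    col = records[exposure]
    if kind == "hyperglycemia":
        return pd.DataFrame({
            f"{exposure}[mild]": (col == "mild").astype(float),
            f"{exposure}[severe]": (col == "severe").astype(float),
        })
    if kind == "binary":
        return pd.DataFrame({f"{exposure}[high]": col.astype(float)})
    levels = sorted(int(v) for v in col.unique() if int(v) != ref)
    return pd.DataFrame({f"{exposure}[{k}]": (col.astype(int) == k).astype(float)
                         for k in levels})


def _adjustment_design(records: pd.DataFrame, covariates) -> pd.DataFrame:
    out = {}
    for c in covariates:
        col = records[c]
        if col.dtype == object:
            for lev in sorted(col.unique())[1:]:
                out[f"{c}[{lev}]"] = (col == lev).astype(float)
        else:
            out[c] = col.astype(float)
    return pd.DataFrame(out, index=records.index)


def run_single_model(records: pd.DataFrame, exposure: str,
                     covariates=()) -> LogisticFit:
    """One logistic fit of pod on a dummy-coded exposure + adjustment set,
    complete-case on the columns involved."""
    cols = ["pod", exposure, *covariates]
    data = records[cols].dropna()
    design = pd.concat([_exposure_design(data, exposure),
                        _adjustment_design(data, covariates)], axis=1)
    return fit_logistic(data["pod"], design)


def run_model_ladder(records: pd.DataFrame, exposure: str,
                     models=(1, 2, 3, 4, 5)) -> pd.DataFrame:
    """Model 1-5 odds-ratio table for one exposure (mirrors the published
    nested-adjustment layout)."""
    rows = []
    for mid in models:
        if mid not in MODEL_ADJUSTMENTS:
            raise ValueError(f"unknown model id {mid}")
        try:
            fit = run_single_model(records, exposure, MODEL_ADJUSTMENTS[mid])
        except (SeparationError, ValueError) as exc:
            raise type(exc)(f"model {mid}: {exc}") from exc
        for term in fit.terms:
            if term.startswith(f"{exposure}["):
                r = fit.or_row(term)
                rows.append({"exposure": exposure, "model": mid,
                             "term": term, "or": r["or"],
                             "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                             "p": r["p"], "n_obs": fit.n_obs})
    return pd.DataFrame(rows)


def screen_covariates(records: pd.DataFrame, candidates,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Univariate logistic screen of candidate covariates against pod.

    One model per candidate; a covariate is selected when its (smallest,
    for multi-level factors) Wald p-value is below ``alpha``. No
    multiplicity adjustment. Constant covariates are skipped with a
    warning.
    """
    rows = []
    for cand in candidates:
        data = records[["pod", cand]].dropna()
        if data[cand].nunique() < 2:
            warnings.warn(f"covariate {cand!r} has no variance; skipped")
            continue
        design = _adjustment_design(data, [cand])
        fit = fit_logistic(data["pod"], design)
        p = float(fit.table.drop(index="const")["p"].min())
        rows.append({"covariate": cand, "p": p, "selected": p < alpha})
    return pd.DataFrame(rows)


def subgroup_analysis(records: pd.DataFrame, exposure: str, subgroup: str,
                      cutpoint=None) -> pd.DataFrame:
    """Per-stratum exposure ORs, adjusted for the full (Model 5) set minus
    the stratifying variable.

    ``subgroup`` is a key of :data:`SUBGROUP_DEFS` or a records column;
    continuous subgroups are split at ``cutpoint`` (defaults: age 65,
    eGFR 60, INR 1.5). A stratum where the fit is impossible (e.g. zero
    events) is flagged inestimable rather than raising.
    """
    col, default_cut = SUBGROUP_DEFS.get(subgroup, (subgroup, None))
    cutpoint = cutpoint if cutpoint is not None else default_cut
    values = records[col]
    if cutpoint is not None:
        strata = {f"{col}<{cutpoint:g}": values < cutpoint,
                  f"{col}>={cutpoint:g}": values >= cutpoint}
    else:
        strata = {f"{col}={lev}": values == lev
                  for lev in sorted(values.unique(), key=str)}
    adj = tuple(c for c in MODEL_ADJUSTMENTS[5] if c != col)
    rows = []
    for label, mask in strata.items():
        sub = records[mask]
        try:
            fit = run_single_model(sub, exposure, adj)
            for term in fit.terms:
                if term.startswith(f"{exposure}["):
                    r = fit.or_row(term)
                    rows.append({"subgroup": label, "term": term,
                                 "or": r["or"], "ci_low": r["ci_low"],
                                 "ci_high": r["ci_high"], "p": r["p"],
                                 "n_obs": fit.n_obs, "estimable": True})
        except (SeparationError, ValueError, np.linalg.LinAlgError):
            rows.append({"subgroup": label, "term": None, "or": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "n_obs": int(mask.sum()), "estimable": False})
    return pd.DataFrame(rows)


def expand_counts(table_2xc: np.ndarray, levels) -> pd.DataFrame:
    """Patient-level frame from contingency counts.

    ``table_2xc[g, j]`` is the count of outcome group g (0 = no event,
    1 = event) at exposure level ``levels[j]``. Used to rerun the logistic
    and chi-square engines on published summary counts.
    """
    obs = np.asarray(table_2xc, dtype=int)
    rows = []
    for g in (0, 1):
        for j, lev in enumerate(levels):
            rows.extend({"pod": g, "exposure": lev} for _ in range(obs[g, j]))
    return pd.DataFrame(rows)


def or_from_counts(table_2xc: np.ndarray, levels, reference) -> pd.DataFrame:
    """Unadjusted exposure ORs recomputed from contingency counts via the
    logistic engine (one dummy per non-reference level)."""
    data = expand_counts(table_2xc, levels)
    design = pd.DataFrame({
        f"exposure[{lev}]": (data["exposure"] == lev).astype(float)
        for lev in levels if lev != reference})
    fit = fit_logistic(data["pod"], design)
    out = fit.table.drop(index="const").copy()
    out.index = [lev for lev in levels if lev != reference]
    return out
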