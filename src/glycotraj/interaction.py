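"""Additive interaction between dichotomized exposures on the odds-ratio scale.

For a binary exposure E and binary modifier M, a logistic model with the
three joint-category dummies (E+M-, E-M+, E+M+ versus the doubly-unexposed
reference) yields ORs OR10, OR01, OR11, from which

    RERI = OR11 - OR10 - OR01 + 1      (relative excess risk due to
                                        interaction; 0 under additivity)
    AP   = RERI / OR11                 (attributable proportion)

Confidence intervals use the delta method on the three log-odds
coefficients with the fitted covariance (the Hosmer-Lemeshow approach), or
a patient-level nonparametric bootstrap with percentile intervals. An
interaction is flagged significant when the CI excludes 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import MODEL_ADJUSTMENTS, Z_95, _adjustment_design, fit_logistic

#: Default cutpoints used to dichotomize each axis.
DEFAULT_CUTPOINTS = {"mag": 0.77, "gli": 2.6, "mbg": 140.0,
                     "inr": 1.5, "egfr": 60.0}

#: Exposure/modifier column names in a merged analysis table.
AXIS_COLUMNS = {"mag": "mag_mmol_l_h", "gli": "gli_mmol2_h",
                "mbg": "mbg_mgdl", "inr": "inr", "egfr": "egfr"}

#: Axes where the *low* side is the unfavorable one (low eGFR = impaired).
LOW_IS_EXPOSED = {"egfr"}


@dataclass
class InteractionResult:
    exposure: str
    modifier: str
    or10: float
    or01: float
    or11: float
    or_table: pd.DataFrame
    reri: float
    reri_ci: tuple
    ap: float
    ap_ci: tuple
    method: str
    n_obs: int

    @property
    def significant(self) -> bool:
        """CI-excludes-0 rule on the RERI interval."""
        lo, hi = self.reri_ci
        return (lo > 0 and hi > 0) or (lo < 0 and hi < 0)


def _exposed(values: np.ndarray, axis: str, cutpoint: float) -> np.ndarray:
    """High/low split; <= cutpoint is the low side, and for axes where low
    is the unfavorable state (eGFR) the exposed side is value < cutpoint."""
    v = np.asarray(values, dtype=float)
    if axis in LOW_IS_EXPOSED:
        return v < cutpoint
    return v > cutpoint


def dichotomize_for_interaction(records: pd.DataFrame, exposure: str,
                                modifier: str, cutpoints=None) -> pd.Series:
    """Four mutually exclusive joint categories {ref, e, m, em}.

    Reference = low exposure & favorable modifier (low INR / preserved
    eGFR). Cutpoints default to the published medians/boundaries (MAG 0.77,
    GLI 2.6, MBG 140 mg/dL, INR 1.5, eGFR 60); ``cutpoints="median"``
    instead splits the glycemic axes at this cohort's own medians (the
    convention that produced the published cutoffs), keeping the clinical
    INR/eGFR boundaries.
    """
    cut = dict(DEFAULT_CUTPOINTS)
    if cutpoints == "median":
        for axis in {exposure, modifier} & {"mag", "gli", "mbg"}:
            cut[axis] = float(records[AXIS_COLUMNS[axis]].median())
    elif cutpoints:
        cut.update(cutpoints)
    for axis in (exposure, modifier):
        if axis not in cut:
            raise ValueError(f"no cutpoint for axis {axis!r}")
    e = _exposed(records[AXIS_COLUMNS[exposure]], exposure, cut[exposure])
    m = _exposed(records[AXIS_COLUMNS[modifier]], modifier, cut[modifier])
    cat = np.where(e & m, "em", np.where(e, "e", np.where(m, "m", "ref")))
    return pd.Series(pd.Categorical(cat, categories=["ref", "e", "m", "em"]),
                     index=records.index, name="joint")


def _fit_joint(records, joint, adjust):
    design = pd.DataFrame({
        "e10": (joint == "e").astype(float),
        "e01": (joint == "m").astype(float),
        "e11": (joint == "em").astype(float),
    }, index=records.index)
    if adjust:
        design = pd.concat([design, _adjustment_design(records, adjust)], axis=1)
    return fit_logistic(records["pod"], design)


def _reri_ap_from_fit(fit):
    idx = [fit.terms.index(t) for t in ("e10", "e01", "e11")]
    b = fit.coefficients[idx]
    V = fit.covariance[np.ix_(idx, idx)]
    o10, o01, o11 = np.exp(b)
    reri = o11 - o10 - o01 + 1
    ap = reri / o11
    g_reri = np.array([-o10, -o01, o11])
    g_ap = np.array([-o10 / o11, -o01 / o11, (o10 + o01 - 1) / o11])
    se_reri = float(np.sqrt(g_reri @ V @ g_reri))
    se_ap = float(np.sqrt(g_ap @ V @ g_ap))
    return (o10, o01, o11, reri, ap,
            (reri - Z_95 * se_reri, reri + Z_95 * se_reri),
            (ap - Z_95 * se_ap, ap + Z_95 * se_ap))


def compute_reri_ap(records: pd.DataFrame, exposure: str, modifier: str,
                    cutpoints=None, adjust="model5", method: str = "delta",
                    n_boot: int = 500, seed: int = 0) -> InteractionResult:
    """RERI and AP for one exposure-modifier pair.

    ``adjust="model5"`` uses the full adjustment set minus the modifier
    itself (an explicit covariate tuple or () is also accepted). Raises
    ``ValueError`` when any joint cell has zero events, where the joint
    ORs are inestimable.
    """
    if adjust == "model5":
        drop = {AXIS_COLUMNS.get(modifier, modifier)}
        adjust = tuple(c for c in MODEL_ADJUSTMENTS[5] if c not in drop)
    adjust = tuple(adjust)
    cols = ["pod", AXIS_COLUMNS[exposure], AXIS_COLUMNS[modifier], *adjust]
    data = records[list(dict.fromkeys(cols))].dropna().reset_index(drop=True)
    joint = dichotomize_for_interaction(data, exposure, modifier, cutpoints)
    events = data.groupby(joint, observed=False)["pod"].sum()
    if (events == 0).any() or joint.value_counts().min() == 0:
        raise ValueError("inestimable joint OR: a joint cell has zero events")
    fit = _fit_joint(data, joint, adjust)
    o10, o01, o11, reri, ap, reri_ci, ap_ci = _reri_ap_from_fit(fit)

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        reris, aps = [], []
        n = len(data)
        while len(reris) < n_boot:
            take = rng.integers(0, n, n)
            d = data.iloc[take].reset_index(drop=True)
            j = dichotomize_for_interaction(d, exposure, modifier, cutpoints)
            if d.groupby(j, observed=False)["pod"].sum().min() == 0:
                continue
            try:
                f = _fit_joint(d, j, adjust)
            except Exception:
                continue
            _, _, _, r, a, _, _ = _reri_ap_from_fit(f)
            reris.append(r)
            aps.append(a)
        reri_ci = tuple(np.percentile(reris, [2.5, 97.5]))
        ap_ci = tuple(np.percentile(aps, [2.5, 97.5]))
    elif method != "delta":
        raise ValueError(f"unknown method {method!r}")

    sub = fit.table.loc[["e10", "e01", "e11"]].copy()
    sub.index = [f"high {exposure} & low {modifier}",
                 f"low {exposure} & high {modifier}",
                 f"high {exposure} & high {modifier}"]
    return InteractionResult(exposure=exposure, modifier=modifier,
                             or10=o10, or01=o01, or11=o11, or_table=sub,
                             reri=reri, reri_ci=reri_ci, ap=ap, ap_ci=ap_ci,
                             method=method, n_obs=fit.n_obs)


def reri_ap_closed_form(or10: float, or01: float, or11: float):
    """RERI and AP from three joint ORs (no uncertainty).

    The closed-form identities: additive effects (OR11 = OR10 + OR01 - 1)
    give RERI = 0, and AP = RERI / OR11.
    """
    if or11 <= 0:
        raise ValueError("OR11 must be positive")
    reri = or11 - or10 - or01 + 1
    return reri, reri / or11


def interaction_table(records: pd.DataFrame, pairs, cutpoints=None,
                      adjust="model5", method="delta", n_boot=500,
                      seed=0) -> pd.DataFrame:
    """Run several exposure:modifier pairs; one summary row per pair.

    A pair whose joint ORs are inestimable (an empty joint cell, or a
    separated fit) is flagged rather than aborting the whole table.
    """
    from .association import SeparationError

    rows = []
    for exposure, modifier in pairs:
        base = {"exposure": exposure, "modifier": modifier}
        try:
            res = compute_reri_ap(records, exposure, modifier,
                                  cutpoints=cutpoints, adjust=adjust,
                                  method=method, n_boot=n_boot, seed=seed)
        except (ValueError, SeparationError) as exc:
            rows.append({**base, "or10": np.nan, "or01": np.nan,
                         "or11": np.nan, "reri": np.nan, "reri_lo": np.nan,
                         "reri_hi": np.nan, "ap": np.nan, "ap_lo": np.nan,
                         "ap_hi": np.nan, "significant": False,
                         "n_obs": len(records), "estimable": False,
                         "note": str(exc)})
            continue
        rows.append({**base, "or10": res.or10, "or01": res.or01,
                     "or11": res.or11, "reri": res.reri,
                     "reri_lo": res.reri_ci[0], "reri_hi": res.reri_ci[1],
                     "ap": res.ap, "ap_lo": res.ap_ci[0],
                     "ap_hi": res.ap_ci[1], "significant": res.significant,
                     "n_obs": res.n_obs, "estimable": True, "note": ""})
    return pd.DataFrame(rows)
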