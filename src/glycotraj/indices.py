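"""Glycemic variability indices over a 24-h ICU glucose series.

Works on one patient's short glucose profile (canonically six readings at
4-h intervals, T1..T6) and derives:

* baseline glucose — the first reading (mg/dL);
* MBG — mean blood glucose (mg/dL);
* MAG — mean absolute glucose change rate, ``sum(|dG|) / sum(dt)``
  (mmol/L per h);
* MAGE — mean amplitude of glycemic excursions: the mean of the absolute
  adjacent peak-valley differences that exceed one (sample) standard
  deviation of the series (mmol/L);
* GLI — glycemic lability index, ``sum(dG_mmol^2 / dt_h)`` ((mmol/L)^2/h);
* LAGE — largest amplitude of glycemic excursion, ``max - min`` (mg/dL).

Categorical strata follow the conventional cutoffs used in ICU delirium
cohort work: the 3-level hyperglycemia scale for baseline glucose and MBG
(<140, [140, 200), >=200 mg/dL) and high/low dichotomies at cohort medians
for MAG, MAGE, GLI and LAGE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: mg/dL per mmol/L for glucose (molar mass 180.16 g/mol).
MGDL_PER_MMOLL = 18.016

#: Hyperglycemia boundaries for baseline glucose and MBG, mg/dL.
HYPERGLYCEMIA_BOUNDS = (140.0, 200.0)

#: Default high/low cutoffs (cohort medians reported for diabetic CABG
#: patients): MAG mmol/L/h, MAGE mmol/L, GLI (mmol/L)^2/h, LAGE mg/dL.
DEFAULT_THRESHOLDS = {"mag": 0.77, "mage": 2.58, "gli": 2.6, "lage": 79.2}

HYPERGLYCEMIA_LEVELS = ("no", "mild", "severe")


class InsufficientReadingsError(ValueError):
    """Raised when a series has too few readings for the requested index."""


def mgdl_to_mmoll(value):
    """Convert glucose from mg/dL to mmol/L (divide by 18.016).

    Accepts scalars or arrays; negative input raises ``ValueError``.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("glucose cannot be negative")
    out = arr / MGDL_PER_MMOLL
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


@dataclass
class GlucoseSeries:
    """One patient's timestamped glucose readings within 24 h of admission.

    ``times`` are hours since ICU admission; readings are sorted by time on
    construction (defensive), then required to be strictly increasing.
    """

    patient_id: object
    times: np.ndarray
    values_mgdl: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values_mgdl, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if t.size < 2:
            raise InsufficientReadingsError(
                f"patient {self.patient_id}: need >=2 readings, got {t.size}"
            )
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"patient {self.patient_id}: duplicate reading times")
        if np.any(v <= 0):
            raise ValueError(f"patient {self.patient_id}: non-positive glucose value")
        if t[-1] - t[0] > 24.0:
            raise ValueError(f"patient {self.patient_id}: series spans more than 24 h")
        self.times = t
        self.values_mgdl = v

    def __len__(self) -> int:
        return self.times.size


def compute_mbg(series: GlucoseSeries) -> float:
    """Mean blood glucose in mg/dL (arithmetic mean of the readings)."""
    return float(np.mean(series.values_mgdl))


def compute_lage(series: GlucoseSeries) -> float:
    """Largest amplitude of glycemic excursion, max - min, in mg/dL."""
    return float(np.max(series.values_mgdl) - np.min(series.values_mgdl))


def compute_mag(series: GlucoseSeries) -> float:
    """Mean absolute glucose change rate in mmol/L/h.

    ``sum over consecutive pairs of |dG| (mmol/L) / sum of dt (h)``, using the
    actual charted times (with the canonical 6-point 4-h grid the denominator
    is 20 h).
    """
    dt = np.diff(series.times)
    total = float(dt.sum())
    if total <= 0:
        raise ValueError("zero total time span")
    dg = np.abs(np.diff(mgdl_to_mmoll(series.values_mgdl)))
    return float(dg.sum() / total)


def compute_gli(series: GlucoseSeries) -> float:
    """Glycemic lability index in (mmol/L)^2/h.

    Sum over consecutive reading pairs of the squared glucose difference
    (mmol/L) divided by the elapsed hours between those readings.
    """
    dt = np.diff(series.times)
    if np.any(dt <= 0):
        raise ValueError("zero time gap between readings")
    dg = np.diff(mgdl_to_mmoll(series.values_mgdl))
    return float(np.sum(dg * dg / dt))


def _collapse_plateaus(values: np.ndarray) -> np.ndarray:
    """Indices keeping the first point of each run of equal readings."""
    keep = np.ones(values.size, dtype=bool)
    keep[1:] = values[1:] != values[:-1]
    return np.flatnonzero(keep)


def _extrema_indices(values: np.ndarray) -> np.ndarray:
    """Local-extremum indices: endpoints plus interior turning points.

    Plateaus are collapsed to their first index first, so the interior test
    reduces to a sign change of consecutive differences.
    """
    idx = _collapse_plateaus(values)
    v = values[idx]
    if v.size < 3:
        # Constant or two-level series: no interior turning point possible.
        return idx if v.size < 2 else idx[[0, -1]]
    d = np.diff(v)
    turning = np.flatnonzero(d[:-1] * d[1:] < 0) + 1
    return idx[np.concatenate(([0], turning, [v.size - 1]))]


def compute_mage(series: GlucoseSeries) -> float:
    """Mean amplitude of glycemic excursions in mmol/L.

    Sample-SD (n-1) threshold over all readings; excursions are absolute
    differences between adjacent local extrema, counted only when the series
    has at least one interior turning point (a peak-valley alternation);
    monotone or constant series therefore score 0, as does a series whose
    excursions all stay within one SD.
    """
    if len(series) < 3:
        raise InsufficientReadingsError("insufficient readings for MAGE")
    v = mgdl_to_mmoll(series.values_mgdl)
    sd = float(np.std(v, ddof=1))
    ext = _extrema_indices(v)
    if ext.size < 3:
        # no interior turning point -> no peak-valley excursion
        return 0.0
    amps = np.abs(np.diff(v[ext]))
    qualifying = amps[amps > sd]
    return float(np.mean(qualifying)) if qualifying.size else 0.0


@dataclass
class GlycemicIndexSet:
    """Derived indices for one patient, plus categorical strata."""

    patient_id: object
    baseline_mgdl: float
    mbg_mgdl: float
    mag_mmol_l_h: float
    mage_mmol_l: float | None
    gli_mmol2_h: float
    lage_mgdl: float
    n_readings: int
    complete: bool
    strata: dict = field(default_factory=dict)


def stratify_value_hyperglycemia(value_mgdl: float) -> str:
    """3-level hyperglycemia stratum: no (<140), mild [140, 200), severe (>=200)."""
    lo, hi = HYPERGLYCEMIA_BOUNDS
    if value_mgdl < lo:
        return "no"
    return "mild" if value_mgdl < hi else "severe"


def stratify_indexes(index_set: GlycemicIndexSet, thresholds=None) -> dict:
    """Attach categorical strata to an index set.

    ``thresholds`` maps {mag, mage, gli, lage} to cutoffs; the variability
    indices are flagged high iff strictly greater than the cutoff. Defaults
    are the published cohort medians (0.77, 2.58, 2.6, 79.2).
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    missing = [k for k in DEFAULT_THRESHOLDS if thr.get(k) is None]
    if missing:
        raise ValueError(f"missing thresholds: {missing}")
    strata = {
        "baseline_stratum": stratify_value_hyperglycemia(index_set.baseline_mgdl),
        "mbg_stratum": stratify_value_hyperglycemia(index_set.mbg_mgdl),
        "mag_high": index_set.mag_mmol_l_h > thr["mag"],
        "gli_high": index_set.gli_mmol2_h > thr["gli"],
        "lage_high": index_set.lage_mgdl > thr["lage"],
        "mage_high": (
            None if index_set.mage_mmol_l is None
            else index_set.mage_mmol_l > thr["mage"]
        ),
    }
    index_set.strata = strata
    return strata


def compute_indices(series: GlucoseSeries, expected_n: int = 6) -> GlycemicIndexSet:
    """All indices for one series; MAGE is None with fewer than 3 readings."""
    mage = compute_mage(series) if len(series) >= 3 else None
    return GlycemicIndexSet(
        patient_id=series.patient_id,
        baseline_mgdl=float(series.values_mgdl[0]),
        mbg_mgdl=compute_mbg(series),
        mag_mmol_l_h=compute_mag(series),
        mage_mmol_l=mage,
        gli_mmol2_h=compute_gli(series),
        lage_mgdl=compute_lage(series),
        n_readings=len(series),
        complete=len(series) >= expected_n,
    )


def cohort_thresholds(index_df: pd.DataFrame) -> dict:
    """Median-mode cutoffs recomputed from a cohort index table."""
    return {
        "mag": float(index_df["mag_mmol_l_h"].median()),
        "mage": float(index_df["mage_mmol_l"].median()),
        "gli": float(index_df["gli_mmol2_h"].median()),
        "lage": float(index_df["lage_mgdl"].median()),
    }


def index_table(glucose_long: pd.DataFrame, thresholds=None,
                threshold_mode: str = "fixed") -> pd.DataFrame:
    """Per-patient index table from a long glucose table.

    Parameters
    ----------
    glucose_long : DataFrame with columns patient_id, time_h, glucose_mgdl.
    thresholds : optional cutoff overrides for the fixed mode.
    threshold_mode : "fixed" (published cutoffs / overrides) or "median"
        (cutoffs recomputed as this cohort's medians).
    """
    rows = []
    for pid, grp in glucose_long.groupby("patient_id", sort=True):
        s = GlucoseSeries(pid, grp["time_h"].to_numpy(), grp["glucose_mgdl"].to_numpy())
        ix = compute_indices(s)
        rows.append({
            "patient_id": pid,
            "baseline_mgdl": ix.baseline_mgdl,
            "mbg_mgdl": ix.mbg_mgdl,
            "mag_mmol_l_h": ix.mag_mmol_l_h,
            "mage_mmol_l": ix.mage_mmol_l,
            "gli_mmol2_h": ix.gli_mmol2_h,
            "lage_mgdl": ix.lage_mgdl,
            "n_readings": ix.n_readings,
            "complete": ix.complete,
        })
    df = pd.DataFrame(rows)
    if threshold_mode == "median":
        thr = cohort_thresholds(df)
    elif threshold_mode == "fixed":
        thr = dict(DEFAULT_THRESHOLDS)
        if thresholds:
            thr.update(thresholds)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    df["baseline_stratum"] = [stratify_value_hyperglycemia(v) for v in df["baseline_mgdl"]]
    df["mbg_stratum"] = [stratify_value_hyperglycemia(v) for v in df["mbg_mgdl"]]
    df["mag_high"] = df["mag_mmol_l_h"] > thr["mag"]
    df["mage_high"] = df["mage_mmol_l"] > thr["mage"]
    df["gli_high"] = df["gli_mmol2_h"] > thr["gli"]
    df["lage_high"] = df["lage_mgdl"] > thr["lage"]
    df.attrs["thresholds"] = thr
    return df
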