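"""Glycemic-index engine: closed-form examples, independent oracles,
and structural invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycotraj.indices import (
    DEFAULT_THRESHOLDS,
    GlucoseSeries,
    InsufficientReadingsError,
    MGDL_PER_MMOLL,
    cohort_thresholds,
    compute_gli,
    compute_indices,
    compute_lage,
    compute_mag,
    compute_mage,
    compute_mbg,
    index_table,
    mgdl_to_mmoll,
    stratify_indexes,
    stratify_value_hyperglycemia,
)

from conftest import random_series


def series(times, values_mmol=None, values_mgdl=None, pid="p"):
    v = (np.asarray(values_mmol) * MGDL_PER_MMOLL if values_mmol is not None
         else np.asarray(values_mgdl, dtype=float))
    return GlucoseSeries(pid, np.asarray(times, dtype=float), v)


# ---------------------------------------------------------------- oracles

def mag_oracle(times, values_mgdl):
    """Loop-based MAG: sum |consecutive difference| in mmol/L over total h."""
    num = 0.0
    for a, b in zip(values_mgdl[:-1], values_mgdl[1:]):
        num += abs(b - a) / MGDL_PER_MMOLL
    return num / (times[-1] - times[0])


def gli_oracle(times, values_mgdl):
    total = 0.0
    for i in range(len(times) - 1):
        d = (values_mgdl[i + 1] - values_mgdl[i]) / MGDL_PER_MMOLL
        total += d * d / (times[i + 1] - times[i])
    return total


def mage_oracle(values_mgdl):
    """Independent MAGE: walk monotone segments, collect turning points.

    Enumerates maximal strictly-monotone runs of the deduplicated series;
    segment boundaries interior to the series are the peaks/valleys. With
    no interior boundary (monotone/constant series) there is no excursion.
    """
    import statistics

    v = [x / MGDL_PER_MMOLL for x in values_mgdl]
    sd = statistics.stdev(v)
    dedup = [v[0]]
    for x in v[1:]:
        if x != dedup[-1]:
            dedup.append(x)
    if len(dedup) < 3:
        return 0.0
    # segment boundaries: positions where direction flips
    extrema = [dedup[0]]
    for i in range(1, len(dedup) - 1):
        rising_in = dedup[i] > dedup[i - 1]
        rising_out = dedup[i + 1] > dedup[i]
        if rising_in != rising_out:
            extrema.append(dedup[i])
    extrema.append(dedup[-1])
    if len(extrema) < 3:
        return 0.0  # no interior turning point -> monotone path
    amps = [abs(b - a) for a, b in zip(extrema[:-1], extrema[1:]) if abs(b - a) > sd]
    return sum(amps) / len(amps) if amps else 0.0


# ------------------------------------------------------------ unit checks

def test_unit_conversion():
    assert mgdl_to_mmoll(0) == 0
    assert mgdl_to_mmoll(180.16) == pytest.approx(10.0)
    assert mgdl_to_mmoll(140) == pytest.approx(7.771, abs=1e-3)
    with pytest.raises(ValueError):
        mgdl_to_mmoll(-1)


@pytest.mark.parametrize("values,expected_mbg,expected_lage", [
    ([140] * 6, 140.0, 0.0),
    ([120, 130, 140, 150, 160, 170], 145.0, 50.0),
])
def test_mbg_lage_closed_form(values, expected_mbg, expected_lage):
    s = series(np.arange(0, 24, 4), values_mgdl=values)
    assert compute_mbg(s) == pytest.approx(expected_mbg)
    assert compute_lage(s) == pytest.approx(expected_lage)


def test_mag_gli_closed_form():
    s = series([0, 4, 8], values_mmol=[5, 7, 6])
    assert compute_mag(s) == pytest.approx((2 + 1) / 8)
    assert compute_gli(s) == pytest.approx(4 / 4 + 1 / 4)
    flat = series([0, 4, 8, 12], values_mgdl=[150] * 4)
    assert compute_mag(flat) == 0.0
    assert compute_gli(flat) == 0.0


def test_mage_examples():
    alternating = series(np.arange(0, 24, 4), values_mmol=[5, 9, 5, 9, 5, 9])
    assert compute_mage(alternating) == pytest.approx(4.0)
    increasing = series(np.arange(0, 24, 4), values_mgdl=np.linspace(100, 300, 6))
    assert compute_mage(increasing) == 0.0
    constant = series(np.arange(0, 24, 4), values_mgdl=[150] * 6)
    assert compute_mage(constant) == 0.0
    with pytest.raises(InsufficientReadingsError):
        compute_mage(series([0, 4], values_mgdl=[100, 150]))


def test_mage_plateau_collapses_to_single_extremum():
    # 5,9,9,5,9: plateau peak at 9 counted once; SD small enough to qualify
    s = series([0, 4, 8, 12, 16], values_mmol=[5, 9, 9, 5, 9])
    # extrema 5,9,5,9 -> amplitudes 4,4,4, sd ~ 2.19 -> mean 4
    assert compute_mage(s) == pytest.approx(4.0)


def test_series_validation():
    with pytest.raises(ValueError):
        GlucoseSeries("p", [0, 0, 4], [100, 110, 120])     # duplicate time
    with pytest.raises(ValueError):
        GlucoseSeries("p", [0, 4], [100, -5])              # non-positive
    with pytest.raises(ValueError):
        GlucoseSeries("p", [0, 30], [100, 110])            # > 24 h span
    s = GlucoseSeries("p", [8, 0, 4], [3.0, 1.0, 2.0])     # sorted defensively
    assert list(s.values_mgdl) == [1.0, 2.0, 3.0]


# ------------------------------------------------------- oracle agreement

def test_indices_match_oracles_on_random_series():
    rng = np.random.default_rng(7)
    for _ in range(300):
        t, v = random_series(rng)
        s = GlucoseSeries("p", t, v)
        assert compute_mbg(s) == pytest.approx(np.mean(v))
        assert compute_lage(s) == pytest.approx(np.max(v) - np.min(v))
        assert compute_mag(s) == pytest.approx(mag_oracle(s.times, s.values_mgdl))
        assert compute_gli(s) == pytest.approx(gli_oracle(s.times, s.values_mgdl))
        assert compute_mage(s) == pytest.approx(mage_oracle(s.values_mgdl))


def test_mage_matches_oracle_on_tie_heavy_series():
    rng = np.random.default_rng(21)
    for _ in range(500):
        n = int(rng.integers(3, 8))
        t = np.arange(n) * 3.0
        v = rng.choice([100.0, 150.0, 200.0, 250.0], size=n)  # many plateaus
        s = GlucoseSeries("p", t, v)
        assert compute_mage(s) == pytest.approx(mage_oracle(s.values_mgdl))


# ----------------------------------------------------------- invariants

@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 2**32 - 1), st.floats(-50, 200))
def test_translation_and_bound_invariants(seed, shift):
    """MAGE <= LAGE in common units; MAG/GLI/LAGE/MAGE shift-invariant,
    MBG shifts by the added constant."""
    rng = np.random.default_rng(seed)
    t, v = random_series(rng)
    s = GlucoseSeries("p", t, v)
    mage, lage = compute_mage(s), compute_lage(s)
    assert mage <= lage / MGDL_PER_MMOLL + 1e-9
    v2 = v + shift
    if np.all(v2 > 0):
        s2 = GlucoseSeries("p", t, v2)
        assert compute_mag(s2) == pytest.approx(compute_mag(s))
        assert compute_gli(s2) == pytest.approx(compute_gli(s))
        assert compute_lage(s2) == pytest.approx(lage)
        assert compute_mage(s2) == pytest.approx(mage)
        assert compute_mbg(s2) == pytest.approx(compute_mbg(s) + shift)


def test_row_order_invariance():
    rng = np.random.default_rng(3)
    t, v = random_series(rng, 6)
    perm = rng.permutation(6)
    a = compute_indices(GlucoseSeries("p", t, v))
    b = compute_indices(GlucoseSeries("p", t[perm], v[perm]))
    assert a.mbg_mgdl == pytest.approx(b.mbg_mgdl)
    assert a.mage_mmol_l == pytest.approx(b.mage_mmol_l)
    assert a.gli_mmol2_h == pytest.approx(b.gli_mmol2_h)


# -------------------------------------------------------------- strata

@pytest.mark.parametrize("value,stratum", [
    (139.9, "no"), (140.0, "mild"), (199.99, "mild"), (200.0, "severe"),
])
def test_hyperglycemia_boundaries(value, stratum):
    assert stratify_value_hyperglycemia(value) == stratum


def test_variability_thresholds_strictly_greater():
    s = series(np.arange(0, 24, 4), values_mgdl=[150, 180, 140, 190, 150, 180])
    ix = compute_indices(s)
    ix.mag_mmol_l_h = 0.77
    assert not stratify_indexes(ix)["mag_high"]
    ix.mag_mmol_l_h = 0.7701
    assert stratify_indexes(ix)["mag_high"]
    with pytest.raises(ValueError):
        stratify_indexes(ix, {"mag": None})


def test_median_mode_thresholds():
    rng = np.random.default_rng(5)
    rows = []
    for pid in range(40):
        t, v = random_series(rng, 6)
        for ti, vi in zip(t, v):
            rows.append({"patient_id": pid, "time_h": ti, "glucose_mgdl": vi})
    long = pd.DataFrame(rows)
    df = index_table(long, threshold_mode="median")
    thr = df.attrs["thresholds"]
    assert thr["mag"] == pytest.approx(df["mag_mmol_l_h"].median())
    # with an even cohort, exactly half strictly exceed the median cutoff
    assert (df["mag_high"].sum()) == 20
    fixed = index_table(long, threshold_mode="fixed")
    assert fixed.attrs["thresholds"] == DEFAULT_THRESHOLDS
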