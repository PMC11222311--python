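"""Descriptive statistics, chi-square, logistic engine, model ladder,
screening and subgroup machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from glycotraj.association import (
    MODEL_ADJUSTMENTS,
    SeparationError,
    chisq_test,
    describe_cohort,
    expand_counts,
    fit_logistic,
    mann_whitney,
    or_from_counts,
    run_model_ladder,
    run_single_model,
    screen_covariates,
    subgroup_analysis,
)
from glycotraj.datasets import CONTINGENCY_COUNTS


def chisq_oracle(obs):
    """Textbook Pearson statistic sum (O-E)^2 / E."""
    obs = np.asarray(obs, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row * col / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


def test_chisq_matches_textbook_oracle_on_random_tables():
    rng = np.random.default_rng(11)
    for _ in range(50):
        obs = rng.integers(1, 200, size=(2, int(rng.integers(2, 5))))
        stat, dof, p = chisq_test(obs)
        assert stat == pytest.approx(chisq_oracle(obs))
        assert dof == obs.shape[1] - 1
        # row/column permutation invariance
        stat2, _, _ = chisq_test(obs[::-1, ::-1])
        assert stat2 == pytest.approx(stat)


def test_chisq_proportional_rows_zero_and_errors():
    stat, _, p = chisq_test([[10, 20, 30], [20, 40, 60]])
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        chisq_test([[1, 0], [2, 0]])
    with pytest.raises(ValueError):
        chisq_test([[1, 2]])


def test_mann_whitney_identical_groups():
    x = np.arange(20.0)
    z, p = mann_whitney(x, x)
    assert z == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    # event group stochastically larger -> negative Z
    z2, p2 = mann_whitney(np.arange(50.0), np.arange(50.0) + 30)
    assert z2 < 0 and p2 < 0.01


def test_describe_cohort_reproduces_published_mbg_chisq():
    levels, _, tab = CONTINGENCY_COUNTS["mbg"]
    data = expand_counts(tab, levels)
    data = data.rename(columns={"exposure": "mbg_stratum"})
    data["noise"] = np.random.default_rng(0).normal(size=len(data))
    rep = describe_cohort(data, "pod", continuous=["noise"],
                          categorical=["mbg_stratum"])
    chi_rows = rep[rep["variable"] == "mbg_stratum"]
    assert chi_rows["statistic"].iloc[0] == pytest.approx(23.478, abs=0.01)
    assert (chi_rows["df"] == 2).all()


def test_describe_cohort_skips_all_missing():
    df = pd.DataFrame({"pod": [0, 1] * 10, "x": [np.nan] * 20})
    with pytest.warns(UserWarning, match="all-missing"):
        rep = describe_cohort(df, "pod", continuous=["x"])
    assert rep.empty


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(5, 400), st.integers(5, 400), st.integers(5, 400),
       st.integers(5, 400))
def test_2x2_logistic_equals_cross_product_ratio(a, b, c, d):
    """Exposure OR from the logistic engine equals ad/bc, and the Wald SE
    equals sqrt(1/a + 1/b + 1/c + 1/d)."""
    tab = np.array([[a, b], [c, d]])  # rows: non-event, event; cols: low, high
    out = or_from_counts(tab, ("low", "high"), "low")
    expected_or = (d / c) / (b / a)
    assert out.loc["high", "or"] == pytest.approx(expected_or, rel=1e-6)
    assert out.loc["high", "se"] == pytest.approx(
        np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), rel=1e-4)


def test_balanced_independent_exposure_or_is_one():
    tab = np.array([[40, 40], [15, 15]])
    out = or_from_counts(tab, ("low", "high"), "low")
    assert out.loc["high", "or"] == pytest.approx(1.0)


def test_separation_and_collinearity_errors():
    n = 60
    x = np.r_[np.zeros(30), np.ones(30)]
    y = x.copy()  # perfectly separated
    with pytest.raises(SeparationError):
        fit_logistic(y, pd.DataFrame({"x": x}))
    rng = np.random.default_rng(0)
    y2 = rng.binomial(1, 0.4, n)
    with pytest.raises(ValueError, match="x2"):
        fit_logistic(y2, pd.DataFrame({"x1": x, "x2": 2 * x}))


def _synthetic_records(n=4000, seed=0, beta_exposure=np.log(2.0)):
    """Records with a known exposure effect and mild confounding."""
    rng = np.random.default_rng(seed)
    rec = pd.DataFrame({
        "age": rng.normal(68, 9, n),
        "hr": rng.normal(81, 9, n),
        "spo2": rng.normal(99, 1.3, n),
        "rdw": rng.normal(13.7, 1.1, n),
        "hematocrit": rng.normal(29, 6, n),
        "egfr": rng.normal(81, 23, n),
        "inr": rng.lognormal(np.log(1.4), 0.15, n),
        "pt": rng.normal(15.2, 2, n),
        "bun": rng.lognormal(np.log(17.5), 0.4, n),
        "bicarbonate": rng.normal(23.3, 2.4, n),
        "na": rng.normal(135.5, 2.4, n),
        "sofa": rng.normal(3, 2, n),
        "cci": rng.normal(3.4, 1.8, n),
        "sepsis": rng.binomial(1, 0.4, n),
        "ckd": rng.binomial(1, 0.2, n),
        "mech_vent": rng.binomial(1, 0.6, n),
        "vasopressor": rng.binomial(1, 0.8, n),
        "gender": rng.choice(["male", "female"], n),
        "race": rng.choice(["white", "other"], n, p=[0.7, 0.3]),
    })
    rec["mag_high"] = rng.binomial(1, expit(0.05 * (rec["age"] - 68))).astype(bool)
    lp = (-2.6 + beta_exposure * rec["mag_high"] + 0.03 * (rec["age"] - 68)
          + 0.3 * rec["sepsis"])
    rec["pod"] = rng.binomial(1, expit(lp))
    return rec


def test_model_ladder_recovers_known_exposure_effect():
    rec = _synthetic_records()
    ladder = run_model_ladder(rec, "mag_high", models=(1, 5))
    m5 = ladder[ladder["model"] == 5].iloc[0]
    fit = run_single_model(rec, "mag_high", MODEL_ADJUSTMENTS[5])
    row = fit.or_row("mag_high[high]")
    se = row["se"]
    assert abs(row["coef"] - np.log(2.0)) < 3 * se
    assert m5["or"] == pytest.approx(row["or"])
    # ladder is structurally monotone: each spec contains the previous
    for m in range(2, 6):
        assert set(MODEL_ADJUSTMENTS[m - 1]) <= set(MODEL_ADJUSTMENTS[m])


def test_model1_equals_model1_with_empty_adjustment():
    rec = _synthetic_records(n=1000, seed=3)
    a = run_single_model(rec, "mag_high", ())
    b = run_single_model(rec, "mag_high", MODEL_ADJUSTMENTS[1])
    np.testing.assert_allclose(a.coefficients, b.coefficients)


def test_orthogonal_covariate_barely_moves_exposure_or():
    rec = _synthetic_records(n=6000, seed=5)
    rng = np.random.default_rng(9)
    rec["noise_cov"] = rng.normal(size=len(rec))
    base = run_single_model(rec, "mag_high", ())
    plus = run_single_model(rec, "mag_high", ("noise_cov",))
    se = base.or_row("mag_high[high]")["se"]
    assert abs(plus.or_row("mag_high[high]")["coef"]
               - base.or_row("mag_high[high]")["coef"]) < 3 * se


def test_screening_selects_signal_and_controls_type_i_rate():
    rec = _synthetic_records(n=3000, seed=7)
    rng = np.random.default_rng(13)
    noise_cols = []
    for j in range(400):
        col = f"z{j:03d}"
        rec[col] = rng.normal(size=len(rec))
        noise_cols.append(col)
    rec["constant"] = 1.0
    with pytest.warns(UserWarning, match="no variance"):
        out = screen_covariates(rec, ["age", "constant", *noise_cols])
    byname = out.set_index("covariate")
    assert bool(byname.loc["age", "selected"])  # true generating covariate
    rate = byname.loc[noise_cols, "selected"].mean()
    se = np.sqrt(0.05 * 0.95 / len(noise_cols))
    assert abs(rate - 0.05) < 3 * se
    assert "constant" not in byname.index


def test_subgroup_partition_and_planted_heterogeneity():
    rec = _synthetic_records(n=6000, seed=1)
    # plant a stronger exposure effect in the young stratum
    rng = np.random.default_rng(2)
    young = rec["age"] < 65
    lp = (-2.6 + np.where(young, np.log(3.0), np.log(1.3)) * rec["mag_high"]
          + 0.3 * rec["sepsis"])
    rec["pod"] = rng.binomial(1, expit(lp))
    out = subgroup_analysis(rec, "mag_high", "age")
    assert out["n_obs"].sum() == len(rec)  # strata partition the cohort
    est = out.set_index("subgroup")
    lo = np.log(est.loc["age<65", "or"])
    hi = np.log(est.loc["age>=65", "or"])
    assert lo > hi
    # each stratum estimate within 3 SEs of its planted value
    for label, truth in (("age<65", np.log(3.0)), ("age>=65", np.log(1.3))):
        row = est.loc[label]
        se = (np.log(row["ci_high"]) - np.log(row["or"])) / 1.96
        assert abs(np.log(row["or"]) - truth) < 3 * se


def test_subgroup_zero_events_flagged_inestimable():
    rec = _synthetic_records(n=400, seed=4)
    rec.loc[rec["sepsis"] == 1, "pod"] = 0  # no events in the sepsis stratum
    out = subgroup_analysis(rec, "mag_high", "sepsis")
    flags = out.set_index("subgroup")["estimable"]
    assert not flags.loc["sepsis=1"]
    assert flags.loc["sepsis=0"]


def test_subgroup_drops_stratifier_from_adjustment():
    rec = _synthetic_records(n=2000, seed=6)
    out = subgroup_analysis(rec, "mag_high", "inr")
    assert set(out["subgroup"]) == {"inr<1.5", "inr>=1.5"}
    # stratifying on a variable absent from the adjustment set leaves it intact
    out2 = subgroup_analysis(rec, "mag_high", "gender")
    assert out2["estimable"].all()
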