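"""Logistic NTCP model: eligibility, MLE fit, tolerance doses, SE bands."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import tli_ntcp as T
from tli_ntcp.logistic import SeparationError, DEFAULT_PROBABILITY_LEVELS


def binary_frame(doses, events):
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(len(doses))],
        "dose": np.asarray(doses, dtype=float),
        "time_months": np.full(len(doses), 60.0),
        "event": np.asarray(events, dtype=int),
    })


# --- eligibility window -------------------------------------------------------

def test_fifty_month_rule_yields_222_eligible_lobes(eligibility_cohort):
    """132 bilateral patients with 21 censored by death/repeat RT before 50
    months leave 222 analysable lobes (42 excluded)."""
    eligible, counts = T.eligibility_filter(eligibility_cohort, window=50)
    assert counts["n_total"] == 264
    assert counts["n_eligible"] == 222
    assert counts["n_excluded"] == 42
    assert counts["n_injured_kept"] == 21


def test_zero_window_keeps_everything(eligibility_cohort):
    _, counts = T.eligibility_filter(eligibility_cohort, window=0)
    assert counts["n_eligible"] == counts["n_total"]


def test_injury_before_later_censoring_is_retained():
    df = pd.DataFrame({
        "patient_id": ["a", "a"], "side": ["left", "right"],
        "time_months": [19.0, 30.0], "event": [1, 0],
        "censor_reason": [None, "death"],
    })
    eligible, _ = T.eligibility_filter(df, window=50)
    assert (eligible["event"] == 1).sum() == 1          # injured lobe kept
    strict, _ = T.eligibility_filter(df, window=50, strict=True)
    assert len(strict) == 0                              # toggle drops the pair


# --- maximum-likelihood fit ----------------------------------------------------

def test_complete_separation_is_flagged():
    df = binary_frame(np.arange(1, 9), [0, 0, 0, 0, 1, 1, 1, 1])
    with pytest.raises(SeparationError):
        T.fit_logistic(df, "dose")


def test_single_outcome_class_is_an_error():
    with pytest.raises(ValueError, match="both outcome classes"):
        T.fit_logistic(binary_frame([1, 2, 3], [0, 0, 0]), "dose")


def test_null_association_gives_flat_slope():
    """Doses permuted against outcomes: |z| < 2 in >= 90% of replicates."""
    rng = np.random.default_rng(12)
    ok = 0
    n_rep = 50
    for _ in range(n_rep):
        doses = rng.normal(70, 6, 300)
        y = rng.random(300) < 0.15
        fit = T.fit_logistic(binary_frame(doses, y.astype(int)), "dose")
        z = fit.b1 / math.sqrt(fit.covariance[1, 1])
        ok += abs(z) < 2
    assert ok / n_rep >= 0.90


def test_parameter_recovery_from_logistic_truth():
    """n = 5000 simulated from the published-anchor-implied parameters
    (b0, b1) = (-13.17, 0.1628): estimates within 3 SE of truth."""
    b0, b1 = -13.17, 0.1628
    rng = np.random.default_rng(8)
    doses = rng.uniform(45, 100, 5000)
    p = 1 / (1 + np.exp(-(b0 + b1 * doses)))
    y = (rng.random(5000) < p).astype(int)
    fit = T.fit_logistic(binary_frame(doses, y), "dose")
    assert abs(fit.b0 - b0) < 3 * math.sqrt(fit.covariance[0, 0])
    assert abs(fit.b1 - b1) < 3 * math.sqrt(fit.covariance[1, 1])


# --- tolerance doses -----------------------------------------------------------

def test_published_d1cc_anchor_calibration():
    """TD50 = 80.9 and TD10 = 67.4 Gy imply the remaining published D_1cc
    tolerance-dose rows to one decimal."""
    fit = T.logistic_fit_from_anchors([(80.9, 0.50), (67.4, 0.10)])
    assert round(T.tolerance_dose(fit, 0.20)[0], 1) == 72.4
    assert round(T.tolerance_dose(fit, 0.30)[0], 1) == 75.7
    assert round(T.tolerance_dose(fit, 0.05)[0], 1) == 62.8
    assert round(T.tolerance_dose(fit, 0.01)[0], 1) == 52.7


def test_symmetry_point_td50_is_zero_with_zero_intercept():
    fit = T.LogisticFit("dose", 0.0, 0.3, np.zeros((2, 2)), 0, 0)
    assert T.tolerance_dose(fit, 0.5)[0] == 0.0


def test_inverse_identity_probability_of_td():
    fit = T.logistic_fit_from_anchors([(80.9, 0.50), (67.4, 0.10)])
    for p in np.linspace(0.01, 0.99, 33):
        td, _ = T.tolerance_dose(fit, p)
        assert fit.probability(td) == pytest.approx(p, abs=1e-9)


def fitted_on_synthetic(seed=4, shift=0.0):
    rng = np.random.default_rng(seed)
    doses = rng.normal(70, 7, 800) + shift
    p = 1 / (1 + np.exp(-(-13.17 + 0.1628 * (doses - shift))))
    y = (rng.random(800) < p).astype(int)
    return T.fit_logistic(binary_frame(doses, y), "dose")


def test_dose_shift_equivariance():
    """Shifting all doses by +c shifts every TD by +c, SE unchanged."""
    base = fitted_on_synthetic(shift=0.0)
    shifted = fitted_on_synthetic(shift=10.0)
    for p in (0.05, 0.2, 0.5):
        td0, se0 = T.tolerance_dose(base, p)
        td1, se1 = T.tolerance_dose(shifted, p)
        assert td1 - td0 == pytest.approx(10.0, abs=1e-6)
        assert se1 == pytest.approx(se0, rel=1e-6)


def test_delta_method_se_agrees_with_parametric_bootstrap():
    fit = fitted_on_synthetic()
    rng = np.random.default_rng(99)
    draws = rng.multivariate_normal([fit.b0, fit.b1], fit.covariance, 2000)
    for p in (0.2, 0.3, 0.5):
        td, se = T.tolerance_dose(fit, p)
        boot = (math.log(p / (1 - p)) - draws[:, 0]) / draws[:, 1]
        assert se == pytest.approx(boot.std(ddof=1), rel=0.10)


def test_tolerance_table_is_increasing(default_cohort):
    df, _ = default_cohort
    eligible, _ = T.eligibility_filter(df)
    fit = T.fit_logistic(eligible, "d_1cc")
    table = T.tolerance_table(fit)
    assert list(table.rows["p"]) == list(DEFAULT_PROBABILITY_LEVELS)
    assert table.rows["td_gy"].is_monotonic_increasing
    assert (table.rows["se_gy"] > 0).all()


# --- curve and binned incidence ------------------------------------------------

def test_dose_response_curve_shape_and_bands():
    fit = fitted_on_synthetic()
    curve = T.dose_response_curve(fit)
    assert curve["td"].is_monotonic_increasing
    td50 = curve.loc[curve["probability"] == 0.50, "td"].iloc[0]
    assert fit.probability(td50) == pytest.approx(0.5, abs=1e-9)
    se = (curve["td_plus_se"] - curve["td"]).to_numpy()
    p = curve["probability"].to_numpy()
    assert se[p == 0.01][0] > se[p == 0.30][0]   # bands widen toward extremes


def test_binned_incidence_boundaries_and_rates():
    df = binary_frame([69.0, 70.0, 71.0], [0, 1, 0])
    bins = T.binned_incidence(df, "dose", width=2.5)
    assert len(bins) == 2
    first, second = bins.iloc[0], bins.iloc[1]
    assert (first["dose_lo"], first["dose_hi"], first["n"]) == (67.5, 70.0, 1)
    assert (second["dose_lo"], second["dose_hi"], second["n"]) == (70.0, 72.5, 2)
    assert second["crude_rate"] == pytest.approx(0.5)

    single = T.binned_incidence(binary_frame([10, 11, 11.5], [1, 0, 1]),
                                "dose", width=25)
    assert len(single) == 1
    assert single["crude_rate"].iloc[0] == pytest.approx(2 / 3)


def test_binned_rates_bracket_fitted_curve():
    fit = fitted_on_synthetic(seed=10)
    rng = np.random.default_rng(10)
    doses = rng.normal(70, 7, 800)
    p = 1 / (1 + np.exp(-(-13.17 + 0.1628 * doses)))
    y = (rng.random(800) < p).astype(int)
    df = binary_frame(doses, y)
    bins = T.binned_incidence(df, "dose", width=2.5)
    bins = bins[bins["n"] >= 5]
    centre = (bins["dose_lo"] + bins["dose_hi"]) / 2
    model_p = fit.probability(centre.to_numpy())
    sd = np.sqrt(model_p * (1 - model_p) / bins["n"].to_numpy())
    within = np.abs(bins["crude_rate"].to_numpy() - model_p) <= 2 * sd
    assert within.mean() > 0.5
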