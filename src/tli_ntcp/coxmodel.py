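"""Univariate Cox dose-response model and actuarial incidence.

The dose-response route: fit a proportional-hazards model in one dosimetric
variable (per-lobe records), estimate the Breslow baseline cumulative hazard
at covariate zero, and read tolerance doses off the failure function

    F(t | D) = 1 - exp(-H0(t) * exp(beta * D)),

inverted in closed form at a fixed horizon (60 months by default).
Kaplan-Meier TLI-free survival is computed at the patient level (a patient
fails at the earlier injured lobe).

Model fitting is delegated to lifelines (Newton-Raphson partial likelihood,
Efron tie handling, Schoenfeld-residual proportional-hazards test); the
baseline hazard at covariate zero and everything downstream of it is
computed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test

from .records import frame_from_records_or_frame


class CoxFitError(RuntimeError):
    pass


@dataclass
class CoxFit:
    """Fitted univariate Cox dose-response model.

    ``baseline_cum_hazard`` is the Breslow estimate of H0(t) at covariate
    value zero, a non-decreasing step function stored as a Series indexed by
    event time (H0(0) = 0 implicitly).
    """

    dose_variable: str
    beta: float
    se_beta: float
    loglik: float
    baseline_cum_hazard: pd.Series
    n_lobes: int
    n_events: int
    z: float = float("nan")
    p_value: float = float("nan")

    def h0(self, t: float) -> float:
        """H0 evaluated at the largest event time <= t (step convention)."""
        h = self.baseline_cum_hazard
        if t > h.index.max():
            raise ValueError(
                f"t = {t} months beyond last observed time {h.index.max():.1f}; "
                "refusing to extrapolate the baseline hazard")
        vals = h[h.index <= t]
        return float(vals.iloc[-1]) if len(vals) else 0.0


def _as_fit_frame(lobes, dose_variable: str) -> pd.DataFrame:
    df = frame_from_records_or_frame(lobes)
    if dose_variable not in df.columns:
        raise KeyError(f"dose variable {dose_variable!r} not in cohort table")
    return df[[dose_variable, "time_months", "event"]].rename(
        columns={"time_months": "time"})


def _breslow_baseline(time, event, eta, x=None):
    """Breslow cumulative baseline hazard at linear predictor zero.

    Returns (H0 Series indexed by event time, detail dict with the risk-set
    sums needed for delta-method variances: d_s, W_s = sum of exp(eta) over
    the risk set, S1_s = sum of x * exp(eta)).
    """
    order = np.argsort(time, kind="stable")
    t, e, risk = time[order], event[order], np.exp(eta[order])
    xs = x[order] if x is not None else np.zeros_like(t)
    rev_cum = np.cumsum(risk[::-1])[::-1]
    rev_cum_x = np.cumsum((xs * risk)[::-1])[::-1]
    event_times, d_s = np.unique(t[e == 1], return_counts=True)
    pos = np.searchsorted(t, event_times, side="left")
    w_s = rev_cum[pos]
    s1_s = rev_cum_x[pos]
    h0 = pd.Series(np.cumsum(d_s / w_s), index=event_times, name="H0")
    detail = {"event_times": event_times, "d_s": d_s.astype(float),
              "w_s": w_s, "s1_s": s1_s}
    return h0, detail


def fit_cox(lobes, dose_variable: str) -> CoxFit:
    """Newton-Raphson Cox fit (Efron ties) of injury hazard on one dose metric."""
    df = _as_fit_frame(lobes, dose_variable)
    n_events = int(df["event"].sum())
    if n_events < 1:
        raise CoxFitError("no events in cohort")
    x = df[dose_variable].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise CoxFitError("non-finite dose values")
    if np.ptp(x) == 0:
        # degenerate covariate: no information, flagged rather than fitted
        warnings.warn("dose variable is constant; beta = 0 with infinite SE")
        h0, _ = _breslow_baseline(df["time"].to_numpy(), df["event"].to_numpy(),
                                  np.zeros(len(df)))
        return CoxFit(dose_variable, 0.0, math.inf, float("nan"), h0,
                      len(df), n_events)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise CoxFitError(f"Cox fit failed: {exc}") from exc
    beta = float(cph.params_[dose_variable])
    se = float(cph.standard_errors_[dose_variable])
    if abs(beta) * np.ptp(x) > 20:
        # hazard ratio across the observed dose range exceeds e^20
        warnings.warn("monotone partial likelihood suspected (perfect "
                      "separation in time); beta estimate unreliable")
    eta = beta * x
    h0, detail = _breslow_baseline(df["time"].to_numpy(dtype=float),
                                   df["event"].to_numpy(dtype=int), eta, x=x)
    fit = CoxFit(
        dose_variable=dose_variable,
        beta=beta,
        se_beta=se,
        loglik=float(cph.log_likelihood_),
        baseline_cum_hazard=h0,
        n_lobes=len(df),
        n_events=n_events,
        z=beta / se,
        p_value=float(cph.summary.loc[dose_variable, "p"]),
    )
    fit._lifelines = cph          # kept for the PH test
    fit._fit_frame = df
    fit._baseline_detail = detail  # risk-set sums for delta-method TD SEs
    return fit


def cox_tolerance_dose(fit: CoxFit, p: float, t: float = 60.0) -> tuple[float, float]:
    """Tolerance dose from the Cox route with an approximate delta-method SE.

    TD = [ln(-ln(1-p)) - ln H0(t)] / beta.  The variance propagates Var(beta)
    and the Breslow estimator's variance, including the beta-H0 covariance
    through dH0/dbeta = -sum d_s S1_s / W_s^2 (without it the two error
    sources, which are strongly negatively correlated, wildly overstate the
    SE).  The martingale term sum d_s / W_s^2 supplies the baseline noise.
    Labelled approximate: it ignores higher-order curvature of the Breslow
    functional.
    """
    td = invert_tolerance_dose(fit, p, t)
    detail = getattr(fit, "_baseline_detail", None)
    if detail is None or not math.isfinite(fit.se_beta):
        return td, float("nan")
    keep = detail["event_times"] <= t
    d_s, w_s, s1_s = (detail["d_s"][keep], detail["w_s"][keep], detail["s1_s"][keep])
    h0t = fit.h0(t)
    var_beta = fit.se_beta ** 2
    dh0_dbeta = float(-np.sum(d_s * s1_s / w_s ** 2))
    var_h0 = float(np.sum(d_s / w_s ** 2)) + dh0_dbeta ** 2 * var_beta
    cov_h0_beta = dh0_dbeta * var_beta
    grad = np.array([-td / fit.beta, -1.0 / (fit.beta * h0t)])
    cov = np.array([[var_beta, cov_h0_beta], [cov_h0_beta, var_h0]])
    var_td = float(grad @ cov @ grad)
    return td, math.sqrt(max(var_td, 0.0))


def ph_test(fit: CoxFit, lobes=None, time_transform: str = "km"):
    """Global Schoenfeld-residual test of proportional hazards.

    Returns (chi-square statistic, P).  Scaled Schoenfeld residuals are
    regressed on a transform of time (Kaplan-Meier transform by default).
    """
    if fit.n_events < 3:
        raise CoxFitError("PH test unavailable with fewer than 3 events")
    if not math.isfinite(fit.se_beta):
        raise CoxFitError("PH test undefined for a degenerate (constant-dose) fit")
    cph = getattr(fit, "_lifelines", None)
    df = getattr(fit, "_fit_frame", None)
    if cph is None:
        if lobes is None:
            raise CoxFitError("original data required to run the PH test")
        refit = fit_cox(lobes, fit.dose_variable)
        cph, df = refit._lifelines, refit._fit_frame
    res = proportional_hazard_test(cph, df, time_transform=time_transform)
    stat = float(np.asarray(res.test_statistic).ravel()[0])
    p = float(np.asarray(res.p_value).ravel()[0])
    return stat, p


def failure_probability(fit: CoxFit, dose: float, t: float = 60.0) -> float:
    """F(t | D) = 1 - exp(-H0(t) exp(beta D)) with step-function H0."""
    return 1.0 - math.exp(-fit.h0(t) * math.exp(fit.beta * dose))


def invert_tolerance_dose(fit: CoxFit, p: float, t: float = 60.0) -> float:
    """Dose at which the failure probability at horizon t equals p.

    Closed form: D = [ln(-ln(1 - p)) - ln H0(t)] / beta.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if fit.beta == 0:
        raise ValueError("tolerance dose undefined for beta = 0")
    h0t = fit.h0(t)
    if h0t <= 0:
        raise ValueError(f"baseline cumulative hazard is zero at t = {t}")
    if fit.beta < 0:
        warnings.warn("beta < 0: tolerance dose decreases with p")
    return (math.log(-math.log1p(-p)) - math.log(h0t)) / fit.beta


def cox_fit_from_anchors(anchors: list[tuple[float, float]],
                         t: float = 60.0,
                         dose_variable: str = "dose") -> CoxFit:
    """Calibrate (beta, H0(t)) from two (dose, failure probability) anchors.

    Solves ln(-ln(1 - p_i)) = ln H0(t) + beta * D_i exactly for the two
    anchors, returning a CoxFit whose baseline step function has the single
    step H0(t) at t.  Used for worked-example calculations where only
    published failure-function anchor points are available.
    """
    if len(anchors) != 2:
        raise ValueError("exactly two (dose, probability) anchors required")
    (d1, p1), (d2, p2) = anchors
    if d1 == d2:
        raise ValueError("anchor doses must differ")
    y1 = math.log(-math.log1p(-p1))
    y2 = math.log(-math.log1p(-p2))
    beta = (y2 - y1) / (d2 - d1)
    log_h0 = y1 - beta * d1
    h0 = pd.Series([math.exp(log_h0)], index=[float(t)], name="H0")
    return CoxFit(dose_variable, beta, float("nan"), float("nan"), h0,
                  n_lobes=0, n_events=0)


def _patient_level(lobes) -> pd.DataFrame:
    df = frame_from_records_or_frame(lobes)

    def collapse(g):
        if g["event"].any():
            return pd.Series({"time": g.loc[g["event"] == 1, "time_months"].min(),
                              "event": 1})
        return pd.Series({"time": g["time_months"].max(), "event": 0})

    return df.groupby("patient_id").apply(collapse, include_groups=False)


def kaplan_meier(lobes, horizons: tuple[float, ...] = (36.0, 60.0)):
    """Patient-level Kaplan-Meier injury-free survival.

    A patient is an event at the earlier injured lobe's time.  Returns
    (survival step-function DataFrame with Greenwood confidence limits,
    {horizon: injury-free rate}).
    """
    pat = _patient_level(lobes)
    if len(pat) == 0:
        raise ValueError("empty cohort")
    km = KaplanMeierFitter()
    km.fit(pat["time"], event_observed=pat["event"], label="tli_free")
    surv = km.survival_function_.join(km.confidence_interval_)
    surv.columns = ["survival", "ci_lower", "ci_upper"]
    rates = {float(h): float(km.predict(h)) for h in horizons}
    return surv, rates


def failure_curve(fit: CoxFit, dose_grid, t: float = 60.0) -> pd.DataFrame:
    """Failure probability at horizon t over a dose grid (figure export)."""
    return pd.DataFrame({
        "dose_gy": np.asarray(dose_grid, dtype=float),
        f"failure_{int(t)}m": [failure_probability(fit, d, t) for d in dose_grid],
    })
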