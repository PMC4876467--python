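"""Two-parameter logistic NTCP model with maximum-likelihood tolerance doses.

Binary-response route: lobes observed injury-free for longer than an
eligibility window (50 months by default, within which nearly all injuries
manifest) are classed as normal; lobes of patients censored by death or
repeat radiotherapy inside the window are excluded as insufficiently
observed.  The response model is

    p(D) = 1 / (1 + exp(-(b0 + b1 * D)))

fitted by maximum likelihood (IRLS via statsmodels), with the covariance of
(b0, b1) taken from the inverse observed Fisher information.  Tolerance
doses TD_p = (logit(p) - b0)/b1 carry delta-method standard errors, which is
also how the dose-direction (horizontal) error bands of the dose-response
curve are drawn.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import frame_from_records_or_frame

DEFAULT_PROBABILITY_LEVELS = (0.01, 0.05, 0.10, 0.20, 0.30, 0.50)


class SeparationError(RuntimeError):
    """Complete separation: the MLE does not exist (slope diverges)."""


@dataclass
class LogisticFit:
    """Fitted two-parameter logistic dose-response model."""

    dose_variable: str
    b0: float
    b1: float
    covariance: np.ndarray      # 2x2, order (b0, b1)
    n_lobes: int
    n_events: int
    p_values: tuple[float, float] = (float("nan"), float("nan"))

    def probability(self, dose) -> np.ndarray | float:
        eta = self.b0 + self.b1 * np.asarray(dose, dtype=float)
        out = 1.0 / (1.0 + np.exp(-eta))
        return float(out) if out.ndim == 0 else out


@dataclass
class ToleranceTable:
    """Tolerance doses TD_p with standard errors for a set of probabilities."""

    dose_variable: str
    rows: pd.DataFrame          # columns: p, td_gy, se_gy

    def as_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def eligibility_filter(lobes, window: float = 50.0, strict: bool = False):
    """Apply the minimum-observation rule for the binary analysis.

    Keeps every injured lobe (strict=False, the default: an injury observed
    before a later censoring event is a real response); keeps uninjured lobes
    only when follow-up exceeds ``window`` months.  With strict=True, injured
    lobes of patients whose censoring (death / repeat RT) occurred within the
    window are dropped as well.

    Returns (eligible DataFrame, counts dict).
    """
    df = frame_from_records_or_frame(lobes)
    injured = df["event"] == 1
    observed_long_enough = df["time_months"] > window
    if strict:
        bad_patients = set(
            df.loc[(~injured) & (~observed_long_enough)
                   & df["censor_reason"].isin(["death", "repeat_rt"]),
                   "patient_id"])
        keep = (injured | observed_long_enough) & ~df["patient_id"].isin(bad_patients)
    else:
        keep = injured | observed_long_enough
    eligible = df[keep].copy()
    counts = {
        "n_total": len(df),
        "n_eligible": int(keep.sum()),
        "n_excluded": int((~keep).sum()),
        "n_injured_kept": int((injured & keep).sum()),
    }
    return eligible, counts


def _check_separation(dose: np.ndarray, y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    if dose[y == 1].min() > dose[y == 0].max() or dose[y == 1].max() < dose[y == 0].min():
        raise SeparationError(
            "complete separation: cases and controls occupy disjoint dose ranges")


def fit_logistic(lobes, dose_variable: str) -> LogisticFit:
    """Maximum-likelihood logistic fit of injury status on one dose metric."""
    df = frame_from_records_or_frame(lobes)
    dose = df[dose_variable].to_numpy(dtype=float)
    y = df["event"].to_numpy(dtype=int)
    _check_separation(dose, y)
    X = sm.add_constant(dose)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0)
        except Exception as exc:
            raise SeparationError(f"logistic MLE did not converge: {exc}") from exc
    cov = np.asarray(res.cov_params())
    if not np.all(np.isfinite(cov)) or np.abs(res.params[1]) > 1e3:
        raise SeparationError("quasi-separation: unstable slope estimate")
    return LogisticFit(
        dose_variable=dose_variable,
        b0=float(res.params[0]),
        b1=float(res.params[1]),
        covariance=cov,
        n_lobes=len(y),
        n_events=int(y.sum()),
        p_values=(float(res.pvalues[0]), float(res.pvalues[1])),
    )


def logistic_fit_from_anchors(anchors: list[tuple[float, float]],
                              dose_variable: str = "dose") -> LogisticFit:
    """Calibrate (b0, b1) exactly from two (tolerance dose, probability) pairs.

    Solves logit(p_i) = b0 + b1 * TD_i for the two anchors; the covariance is
    zero (the calibration is exact, not estimated).  Used for worked-example
    calculations from published tolerance-dose tables.
    """
    if len(anchors) != 2:
        raise ValueError("exactly two (dose, probability) anchors required")
    (d1, p1), (d2, p2) = anchors
    if d1 == d2:
        raise ValueError("anchor doses must differ")
    l1 = math.log(p1 / (1 - p1))
    l2 = math.log(p2 / (1 - p2))
    b1 = (l2 - l1) / (d2 - d1)
    b0 = l1 - b1 * d1
    return LogisticFit(dose_variable, b0, b1, np.zeros((2, 2)), 0, 0)


def tolerance_dose(fit: LogisticFit, p: float) -> tuple[float, float]:
    """TD_p and its delta-method standard error.

    td = (logit(p) - b0)/b1; the gradient of td w.r.t. (b0, b1) is
    (-1/b1, -td/b1), propagated through the (b0, b1) covariance.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if fit.b1 == 0:
        raise ValueError("tolerance dose undefined for zero slope")
    if fit.b1 < 0:
        warnings.warn("b1 < 0: dose-response is decreasing; TD ordering reversed")
    td = (math.log(p / (1 - p)) - fit.b0) / fit.b1
    grad = np.array([-1.0 / fit.b1, -td / fit.b1])
    var = float(grad @ fit.covariance @ grad)
    return td, math.sqrt(max(var, 0.0))


def tolerance_table(fit: LogisticFit,
                    levels=DEFAULT_PROBABILITY_LEVELS) -> ToleranceTable:
    rows = []
    for p in levels:
        td, se = tolerance_dose(fit, p)
        rows.append({"p": p, "td_gy": td, "se_gy": se})
    return ToleranceTable(fit.dose_variable, pd.DataFrame(rows))


def dose_response_curve(fit: LogisticFit,
                        levels=None) -> pd.DataFrame:
    """Dose-response curve with horizontal (dose-direction) +/-1 SE bands.

    For each probability level the tolerance dose is shifted by +/- its
    delta-method SE, giving rows (probability, td_minus_se, td, td_plus_se).
    This is the fixed-probability convention for error bands on an NTCP
    curve; vertical probability bands can be derived from the same fit by
    propagating (b0, b1) uncertainty at fixed dose.
    """
    if levels is None:
        levels = np.round(np.arange(0.01, 1.00, 0.01), 2)
    rows = []
    for p in levels:
        td, se = tolerance_dose(fit, p)
        rows.append({"probability": p, "td_minus_se": td - se,
                     "td": td, "td_plus_se": td + se})
    return pd.DataFrame(rows)


def binned_incidence(lobes, dose_variable: str, width: float = 2.5) -> pd.DataFrame:
    """Crude incidence in half-open dose bins [k*width, (k+1)*width).

    Empty bins are omitted; rates use lobes as denominators.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    df = frame_from_records_or_frame(lobes)
    dose = df[dose_variable].to_numpy(dtype=float)
    k = np.floor(dose / width).astype(int)
    out = []
    for kk in np.unique(k):
        mask = k == kk
        n = int(mask.sum())
        events = int(df.loc[mask, "event"].sum())
        out.append({
            "dose_lo": kk * width, "dose_hi": (kk + 1) * width,
            "n": n, "events": events, "crude_rate": events / n,
        })
    return pd.DataFrame(out)
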