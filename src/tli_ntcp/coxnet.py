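"""Elastic-net-penalized Cox regression for dosimetric predictor screening.

DVH metrics are strongly rank-correlated (the hottest-volume doses are all
driven by the same hot spot), so subset selection by unpenalized multivariable
Cox regression is unstable.  The screen instead maximises the penalized Cox
partial likelihood

    -(1/n) * logPL(beta)  +  lambda * [ alpha * ||beta||_1
                                        + (1 - alpha)/2 * ||beta||_2^2 ]

by cyclic coordinate descent on the iteratively reweighted quadratic
approximation (Breslow tie handling, warm starts along a decreasing lambda
path), with the mixing weight alpha = 0.5 by default so that correlated
predictors are selected as a group rather than arbitrarily thinned.  The
penalty weight is chosen by K-fold cross-validated partial-likelihood
deviance (Verweij-van Houwelingen), folds split at the patient level and
stratified by event status, using the one-standard-error rule by default.

Predictors are standardized internally; reported coefficients are on the
original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import frame_from_records_or_frame
from .dvh import DoseMetrics

CLINICAL_COLUMNS = ("age", "sex_male", "t_stage_t34", "chemo_yes")


@dataclass
class PredictorMatrix:
    """Standardizable candidate-predictor matrix (one row per lobe).

    Binary covariates are coded 0/1 (T-stage dichotomized T1-2 vs T3-4) and
    standardized like continuous columns for penalization; coefficients are
    back-transformed to the original scale on output.
    """

    X: pd.DataFrame
    patient_ids: np.ndarray | None = None
    center: pd.Series | None = None
    scale: pd.Series | None = None

    def __post_init__(self):
        if self.X.isna().any().any():
            raise ValueError("predictor matrix contains missing values")
        if self.center is None:
            self.center = self.X.mean()
            sd = self.X.std(ddof=0)
            self.scale = sd.where(sd > 0, 1.0)

    @classmethod
    def from_cohort(cls, lobes) -> "PredictorMatrix":
        """Build the 19-column candidate matrix (15 DVH + 4 clinical)."""
        df = frame_from_records_or_frame(lobes)
        X = df[list(DoseMetrics.COLUMNS)].astype(float).copy()
        X["age"] = df["age"].astype(float)
        X["sex_male"] = (df["sex"] == "male").astype(float)
        X["t_stage_t34"] = (df["t_stage"] == "T3-4").astype(float)
        X["chemo_yes"] = (df["chemo"] == "yes").astype(float)
        return cls(X, patient_ids=df["patient_id"].to_numpy())

    def standardized(self) -> np.ndarray:
        return ((self.X - self.center) / self.scale).to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


@dataclass(frozen=True)
class ElasticNetConfig:
    alpha: float = 0.5                 # L1/L2 mixing weight
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-2
    k_folds: int = 10
    selection_rule: str = "min_plus_1se"   # or "min"
    seed: int = 0
    tol: float = 1e-7                  # max coefficient change, standardized scale
    max_sweeps: int = 100_000

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.selection_rule not in ("min", "min_plus_1se"):
            raise ValueError(f"unknown selection rule {self.selection_rule!r}")


@dataclass
class SelectionResult:
    """Elastic-net path, cross-validation curve and the chosen model."""

    variables: list[str]
    lambda_path: np.ndarray
    coefficients: pd.DataFrame          # variables x lambdas, original scale
    cv_mean: np.ndarray | None = None   # CV deviance per lambda
    cv_se: np.ndarray | None = None
    lambda_chosen: float | None = None
    selected_variables: list[str] = field(default_factory=list)
    objective_paths: dict = field(default_factory=dict)  # lambda -> per-sweep objective

    def coefficients_at(self, lam: float) -> pd.Series:
        j = int(np.argmin(np.abs(self.lambda_path - lam)))
        return self.coefficients.iloc[:, j]

    def to_dict(self) -> dict:
        out = {
            "variables": self.variables,
            "lambda_path": self.lambda_path.tolist(),
            "coefficients": self.coefficients.to_dict(orient="list"),
            "lambda_chosen": self.lambda_chosen,
            "selected_variables": self.selected_variables,
        }
        if self.cv_mean is not None:
            out["cv_mean"] = self.cv_mean.tolist()
            out["cv_se"] = self.cv_se.tolist()
        return out


def spearman_matrix(m: PredictorMatrix) -> pd.DataFrame:
    """Spearman rank-correlation matrix of the candidate predictors.

    Average ranks for ties; constant columns yield missing values with a
    warning (their correlation is undefined).
    """
    X = m.X
    if len(X) < 3:
        raise ValueError("need at least 3 rows for rank correlations")
    constant = [c for c in X.columns if X[c].nunique() == 1]
    if constant:
        warnings.warn(f"constant columns have undefined correlations: {constant}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = sps.spearmanr(X.to_numpy()).statistic
    if np.ndim(rho) == 0:   # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    out = pd.DataFrame(rho, index=X.columns, columns=X.columns)
    for c in constant:
        out.loc[c, :] = np.nan
        out.loc[:, c] = np.nan
        out.loc[c, c] = 1.0
    np.fill_diagonal(out.values, 1.0)
    return out


# ---------------------------------------------------------------------------
# penalized Cox partial likelihood machinery (Breslow ties)

def _prepare(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    return time[order], event[order], order


def _log_partial_likelihood(eta, time, event):
    """Breslow log partial likelihood; inputs sorted by time ascending."""
    risk = np.exp(eta)
    w_rev = np.cumsum(risk[::-1])[::-1]     # sum of risk over {t_j >= t_i}
    event_times, d_s = np.unique(time[event == 1], return_counts=True)
    pos = np.searchsorted(time, event_times, side="left")
    return float(eta[event == 1].sum() - np.sum(d_s * np.log(w_rev[pos])))


def _irls_weights(eta, time, event):
    """Gradient u and diagonal-Hessian weights w of logPL w.r.t. eta."""
    risk = np.exp(eta)
    w_rev = np.cumsum(risk[::-1])[::-1]
    event_times, d_s = np.unique(time[event == 1], return_counts=True)
    pos = np.searchsorted(time, event_times, side="left")
    w_s = w_rev[pos]
    d_s = d_s.astype(float)
    c1_steps = np.cumsum(d_s / w_s)
    c2_steps = np.cumsum(d_s / w_s ** 2)
    # for each observation, sum over event times <= its own time
    k = np.searchsorted(event_times, time, side="right")
    c1 = np.where(k > 0, c1_steps[np.maximum(k - 1, 0)], 0.0)
    c2 = np.where(k > 0, c2_steps[np.maximum(k - 1, 0)], 0.0)
    u = event - risk * c1
    w = risk * c1 - risk ** 2 * c2
    w = np.maximum(w, 1e-10)
    return u, w


def _soft_threshold(x, thresh):
    return np.sign(x) * max(abs(x) - thresh, 0.0)


def _penalty(beta, lam, alpha):
    return lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * (beta ** 2).sum())


def _objective(beta, X, time, event, lam, alpha):
    n = len(time)
    return -_log_partial_likelihood(X @ beta, time, event) / n + _penalty(beta, lam, alpha)


def _cd_kernel(X, Xw, r, beta, denom, xwx, thresh, tol, max_sweeps):
    """Cyclic coordinate descent with an active-set strategy.

    Full sweeps alternate with sweeps over the nonzero coordinates until the
    maximum coefficient change falls below tol.  Mutates r and beta in place.
    """
    n, p = X.shape
    sweeps = 0
    while sweeps < max_sweeps:
        # full sweep
        max_delta = 0.0
        for j in range(p):
            bj_old = beta[j]
            rho = 0.0
            for i in range(n):
                rho += Xw[i, j] * r[i]
            rho += xwx[j] * bj_old
            if rho > thresh:
                bj_new = (rho - thresh) / denom[j]
            elif rho < -thresh:
                bj_new = (rho + thresh) / denom[j]
            else:
                bj_new = 0.0
            if bj_new != bj_old:
                diff = bj_old - bj_new
                for i in range(n):
                    r[i] += X[i, j] * diff
                beta[j] = bj_new
                d = abs(bj_new - bj_old)
                if d > max_delta:
                    max_delta = d
        sweeps += 1
        if max_delta < tol:
            break
        # active-set sweeps
        while sweeps < max_sweeps:
            max_delta = 0.0
            for j in range(p):
                bj_old = beta[j]
                if bj_old == 0.0:
                    continue
                rho = 0.0
                for i in range(n):
                    rho += Xw[i, j] * r[i]
                rho += xwx[j] * bj_old
                if rho > thresh:
                    bj_new = (rho - thresh) / denom[j]
                elif rho < -thresh:
                    bj_new = (rho + thresh) / denom[j]
                else:
                    bj_new = 0.0
                if bj_new != bj_old:
                    diff = bj_old - bj_new
                    for i in range(n):
                        r[i] += X[i, j] * diff
                    beta[j] = bj_new
                    d = abs(bj_new - bj_old)
                    if d > max_delta:
                        max_delta = d
            sweeps += 1
            if max_delta < tol:
                break
    return beta


try:  # optional JIT; the pure-Python kernel is the fallback
    from numba import njit as _njit
    _cd_kernel_jit = _njit(cache=False, fastmath=False)(_cd_kernel)
except ImportError:  # pragma: no cover
    _cd_kernel_jit = None


def _cd_solve(X, z, w, beta, lam, alpha, tol, max_sweeps):
    """Solve the penalized weighted least-squares subproblem by CD."""
    n, p = X.shape
    wn = w / n
    Xw = np.ascontiguousarray(wn[:, None] * X)
    r = z - X @ beta
    xwx = (Xw * X).sum(axis=0)
    denom = xwx + lam * (1 - alpha)
    kernel = _cd_kernel_jit or _cd_kernel
    Xc = np.ascontiguousarray(X)
    kernel(Xc, Xw, r, beta, denom, xwx, lam * alpha, tol, max_sweeps)
    return beta


def _fit_single_lambda(X, time, event, lam, alpha, beta0, cfg,
                       track_objective=False):
    """IRLS outer loop with a monotone-objective safeguard (step halving)."""
    beta = beta0.copy()
    obj = _objective(beta, X, time, event, lam, alpha)
    history = [obj]
    for _ in range(50):
        eta = X @ beta
        u, w = _irls_weights(eta, time, event)
        z = eta + u / w
        beta_new = _cd_solve(X, z, w, beta.copy(), lam, alpha, cfg.tol, cfg.max_sweeps)
        # safeguard: the quadratic approximation can overshoot; halve back
        step = 1.0
        for _halving in range(30):
            cand = beta + step * (beta_new - beta)
            obj_new = _objective(cand, X, time, event, lam, alpha)
            if obj_new <= obj + 1e-12:
                break
            step /= 2.0
        else:
            cand, obj_new = beta, obj
        delta = np.max(np.abs(cand - beta)) if len(beta) else 0.0
        beta, obj = cand, obj_new
        history.append(obj)
        if delta < cfg.tol:
            break
    if track_objective:
        return beta, history
    return beta, None


def kkt_residuals(X, time, event, beta, lam, alpha):
    """Subgradient optimality residuals per coordinate (standardized scale).

    At a solution, active coordinates have residual ~0 and inactive ones
    satisfy |gradient| <= lam * alpha.
    """
    n = len(time)
    u, _ = _irls_weights(X @ beta, time, event)
    grad = -(X.T @ u) / n + lam * (1 - alpha) * beta
    res = np.empty_like(beta)
    for j in range(len(beta)):
        if beta[j] != 0:
            res[j] = abs(grad[j] + lam * alpha * np.sign(beta[j]))
        else:
            res[j] = max(abs(grad[j]) - lam * alpha, 0.0)
    return res


def _lambda_path(X, time, event, cfg):
    n = len(time)
    u0, _ = _irls_weights(np.zeros(n), time, event)
    alpha_eff = max(cfg.alpha, 1e-3)
    # tiny inflation so the entry coordinate is exactly zero at the path head
    lam_max = np.max(np.abs(X.T @ u0)) / (n * alpha_eff) * (1.0 + 1e-9)
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)


def fit_coxnet_path(m: PredictorMatrix, outcomes, cfg: ElasticNetConfig | None = None,
                    lambda_path: np.ndarray | None = None,
                    track_objective: bool = False) -> SelectionResult:
    """Fit the whole elastic-net Cox path with warm starts.

    ``outcomes`` is (time, event) arrays or a frame with columns
    time_months/event.  Coefficients are returned on the original predictor
    scale; at the largest path lambda all coefficients are exactly zero.
    """
    cfg = cfg or ElasticNetConfig()
    time, event = _unpack_outcomes(outcomes)
    if event.sum() < 1:
        raise ValueError("no events in outcomes")
    X_std = m.standardized()
    if not np.all(np.isfinite(X_std)):
        raise ValueError("non-finite predictor values")
    t, e, order = _prepare(time, event)
    X = X_std[order]
    if lambda_path is None:
        lambda_path = _lambda_path(X, t, e, cfg)
    p = X.shape[1]
    beta = np.zeros(p)
    coefs = np.zeros((p, len(lambda_path)))
    objective_paths = {}
    for j, lam in enumerate(lambda_path):
        beta, history = _fit_single_lambda(X, t, e, lam, cfg.alpha, beta, cfg,
                                           track_objective=track_objective)
        coefs[:, j] = beta
        if track_objective:
            objective_paths[float(lam)] = history
    scale = m.scale.to_numpy(dtype=float)
    coef_df = pd.DataFrame(coefs / scale[:, None], index=m.columns,
                           columns=[f"lambda_{j}" for j in range(len(lambda_path))])
    return SelectionResult(
        variables=m.columns,
        lambda_path=np.asarray(lambda_path, dtype=float),
        coefficients=coef_df,
        objective_paths=objective_paths,
    )


def _unpack_outcomes(outcomes):
    if isinstance(outcomes, pd.DataFrame):
        return (outcomes["time_months"].to_numpy(dtype=float),
                outcomes["event"].to_numpy(dtype=int))
    time, event = outcomes
    return np.asarray(time, dtype=float), np.asarray(event, dtype=int)


def _patient_folds(patient_ids, patient_event, k, rng):
    """Fold label per patient, stratified by event status."""
    unique = np.asarray(patient_ids)
    folds = {}
    for status in (0, 1):
        pats = [p for p in unique if patient_event[p] == status]
        rng.shuffle(pats)
        for i, p in enumerate(pats):
            folds[p] = i % k
    return folds


def cv_select(m: PredictorMatrix, outcomes, cfg: ElasticNetConfig | None = None) -> SelectionResult:
    """Cross-validated elastic-net Cox selection.

    Folds are split at the patient level (both lobes share a fold) and
    stratified by patient event status; the CV loss is partial-likelihood
    deviance in the Verweij-van Houwelingen form
    dev_k = -2 * [logPL_all(beta^(-k)) - logPL_train(beta^(-k))].
    A held-out fold with zero events triggers a re-draw of the folds with a
    new sub-seed (with a warning).
    """
    cfg = cfg or ElasticNetConfig()
    time, event = _unpack_outcomes(outcomes)
    full = fit_coxnet_path(m, (time, event), cfg)
    lambda_path = full.lambda_path

    if m.patient_ids is None:
        warnings.warn("no patient ids on predictor matrix; folding at lobe level")
        pids = np.arange(len(time)).astype(str)
    else:
        pids = np.asarray(m.patient_ids).astype(str)
    patient_event = pd.Series(event).groupby(pids).max().to_dict()
    unique_patients = list(dict.fromkeys(pids))
    n_event_patients = sum(patient_event[p] for p in unique_patients)
    if cfg.k_folds > max(n_event_patients, 1):
        warnings.warn("more folds than patients with events; CV will be noisy")

    X_std = m.standardized()
    for attempt in range(20):
        rng = np.random.default_rng(cfg.seed + 1000 * attempt)
        fold_of = _patient_folds(unique_patients, patient_event, cfg.k_folds, rng)
        fold_labels = np.array([fold_of[p] for p in pids])
        held_out_events = [event[fold_labels == k].sum() for k in range(cfg.k_folds)]
        if min(held_out_events) >= 1:
            break
        warnings.warn(f"fold with zero events (attempt {attempt}); re-drawing folds")
    dev = np.zeros((cfg.k_folds, len(lambda_path)))
    fold_events = np.zeros(cfg.k_folds)
    t_all, e_all, order_all = _prepare(time, event)
    X_all = X_std[order_all]
    for k in range(cfg.k_folds):
        train = fold_labels != k
        fold_events[k] = event[~train].sum()
        sub = PredictorMatrix(m.X[train], center=m.center, scale=m.scale)
        res_k = fit_coxnet_path(sub, (time[train], event[train]), cfg,
                                lambda_path=lambda_path)
        t_tr, e_tr, order_tr = _prepare(time[train], event[train])
        X_tr = X_std[train][order_tr]
        for j in range(len(lambda_path)):
            beta_orig = res_k.coefficients.iloc[:, j].to_numpy()
            beta_std = beta_orig * m.scale.to_numpy()
            ll_all = _log_partial_likelihood(X_all @ beta_std, t_all, e_all)
            ll_tr = _log_partial_likelihood(X_tr @ beta_std, t_tr, e_tr)
            dev[k, j] = -2.0 * (ll_all - ll_tr)
    # deviance per held-out event, event-weighted across folds: removes the
    # fold-size component from the SE so the 1-SE band reflects model fit
    w_k = np.maximum(fold_events, 1.0)
    cvraw = dev / w_k[:, None]
    cv_mean = np.average(cvraw, axis=0, weights=w_k)
    cv_se = np.sqrt(np.average((cvraw - cv_mean) ** 2, axis=0, weights=w_k)
                    / (cfg.k_folds - 1))
    j_min = int(np.argmin(cv_mean))
    if cfg.selection_rule == "min":
        j_chosen = j_min
    else:
        threshold = cv_mean[j_min] + cv_se[j_min]
        j_chosen = int(np.argmax(cv_mean <= threshold))  # first (largest) lambda within 1 SE
    lam_chosen = float(lambda_path[j_chosen])
    coef_chosen = full.coefficients.iloc[:, j_chosen]
    full.cv_mean = cv_mean
    full.cv_se = cv_se
    full.lambda_chosen = lam_chosen
    full.selected_variables = [v for v in full.variables if coef_chosen[v] != 0.0]
    return full
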