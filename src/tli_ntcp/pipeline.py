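"""End-to-end orchestration: cohort -> screen -> dose-response -> reports.

Stages run in a fixed order, each persisting its artifact (CSV/JSON) into the
output directory before the next starts, so a failed run leaves inspectable
partial results.  Identical config + seed gives a bit-identical report; the
effective configuration, seed and package version are echoed into a
provenance block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .records import read_cohort, write_cohort, cohort_to_frame, frame_from_records_or_frame
from .simulate import CohortConfig, generate_cohort
from .dvh import read_dvh, summarize
from .coxnet import ElasticNetConfig, PredictorMatrix, cv_select
from .coxmodel import fit_cox, ph_test, invert_tolerance_dose, kaplan_meier, failure_curve, CoxFitError
from .logistic import (eligibility_filter, fit_logistic, tolerance_table,
                       dose_response_curve, binned_incidence, SeparationError)
from .stats import crude_rate, baseline_table

log = logging.getLogger("tli_ntcp")

COX_LEVELS = (0.05, 0.10, 0.20, 0.50)
LOGISTIC_LEVELS = (0.01, 0.05, 0.10, 0.20, 0.30, 0.50)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (exactly one input mode)."""

    mode: str = "simulate"                 # simulate | cohort_csv | dvh_dir
    cohort_csv: str | None = None
    dvh_dir: str | None = None
    outcomes_csv: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    elastic_net: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    dose_variables: tuple[str, ...] = ("d_max", "d_1cc")
    horizon: float = 60.0                  # months, Cox failure-function horizon
    km_horizons: tuple[float, ...] = (36.0, 60.0)
    cox_levels: tuple[float, ...] = COX_LEVELS
    logistic_levels: tuple[float, ...] = LOGISTIC_LEVELS
    window: float = 50.0                   # months, logistic eligibility
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self):
        modes = ("simulate", "cohort_csv", "dvh_dir")
        if self.mode not in modes:
            raise ValueError(f"mode must be one of {modes}")
        if self.mode == "cohort_csv" and not self.cohort_csv:
            raise ValueError("cohort_csv mode needs a cohort_csv path")
        if self.mode == "dvh_dir" and not (self.dvh_dir and self.outcomes_csv):
            raise ValueError("dvh_dir mode needs dvh_dir and outcomes_csv")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("cohort", CohortConfig), ("elastic_net", ElasticNetConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = _nested_dataclass(sub, raw[key])
        for key in ("dose_variables", "km_horizons", "cox_levels", "logistic_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))


def _nested_dataclass(cls, raw: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in raw:
            continue
        v = raw[f.name]
        if dataclasses.is_dataclass(f.type) or f.name.endswith("_model"):
            sub = type(getattr(cls(), f.name)) if isinstance(v, dict) else None
            v = sub(**v) if sub else v
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_jsonable(), sort_keys=True).encode()).hexdigest()[:16]


def load_dvh_cohort(dvh_dir, outcomes_csv) -> pd.DataFrame:
    """Assemble a cohort frame from per-structure DVH CSVs plus outcomes.

    The outcomes CSV carries patient_id, side, dvh_file and the clinical and
    outcome columns; dose metrics are computed from each curve.
    """
    dvh_dir = Path(dvh_dir)
    out = pd.read_csv(outcomes_csv)
    rows = []
    for _, r in out.iterrows():
        curve = read_dvh(dvh_dir / r["dvh_file"])
        row = r.drop(labels=["dvh_file"]).to_dict()
        row.update(summarize(curve).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def stage_cohort(config: RunConfig, outdir: Path) -> pd.DataFrame:
    log.info("stage 1: cohort (%s mode)", config.mode)
    if config.mode == "simulate":
        cc = dataclasses.replace(config.cohort, seed=config.seed)
        lobes, truth = generate_cohort(cc)
        write_cohort(lobes, outdir / "cohort.csv")
        (outdir / "truth.json").write_text(json.dumps(truth.as_dict(), indent=2))
        return cohort_to_frame(lobes)
    if config.mode == "cohort_csv":
        df = frame_from_records_or_frame(read_cohort(config.cohort_csv))
    else:
        df = load_dvh_cohort(config.dvh_dir, config.outcomes_csv)
    df.to_csv(outdir / "cohort.csv", index=False)
    return df


def stage_select(config: RunConfig, df: pd.DataFrame, outdir: Path) -> dict:
    log.info("stage 2: elastic-net predictor screen")
    m = PredictorMatrix.from_cohort(df)
    cfg = dataclasses.replace(config.elastic_net, seed=config.seed)
    result = cv_select(m, df, cfg)
    (outdir / "selection.json").write_text(json.dumps(result.to_dict(), indent=2))
    pd.DataFrame({"lambda": result.lambda_path, "cv_deviance": result.cv_mean,
                  "cv_se": result.cv_se}).to_csv(outdir / "cv_curve.csv", index=False)
    return result.to_dict()


def stage_cox(config: RunConfig, df: pd.DataFrame, outdir: Path) -> dict:
    log.info("stage 3: Cox dose-response and actuarial incidence")
    out = {}
    for var in config.dose_variables:
        fit = fit_cox(df, var)
        try:
            ph_chi2, ph_p = ph_test(fit)
        except CoxFitError:
            ph_chi2 = ph_p = float("nan")
        td_rows = []
        for p in config.cox_levels:
            td_rows.append({"p": p, "td_gy": invert_tolerance_dose(fit, p, config.horizon)})
        td = pd.DataFrame(td_rows)
        td.to_csv(outdir / f"cox_td_{var}.csv", index=False)
        grid = np.round(np.arange(40.0, 90.0 + 1e-9, 0.5), 2)
        failure_curve(fit, grid, config.horizon).to_csv(
            outdir / f"cox_failure_curve_{var}.csv", index=False)
        out[var] = {
            "beta": fit.beta, "se_beta": fit.se_beta, "z": fit.z, "p": fit.p_value,
            "n_lobes": fit.n_lobes, "n_events": fit.n_events,
            "ph_chi2": ph_chi2, "ph_p": ph_p,
            "td": {str(r["p"]): r["td_gy"] for r in td_rows},
        }
    surv, rates = kaplan_meier(df, config.km_horizons)
    surv.to_csv(outdir / "km_curve.csv")
    out["km_rates"] = {str(k): v for k, v in rates.items()}
    return out


def stage_logistic(config: RunConfig, df: pd.DataFrame, outdir: Path) -> dict:
    log.info("stage 4: logistic NTCP with %g-month eligibility window", config.window)
    eligible, counts = eligibility_filter(df, window=config.window)
    out = {"eligibility": counts}
    for var in config.dose_variables:
        try:
            fit = fit_logistic(eligible, var)
        except (SeparationError, ValueError) as exc:
            log.warning("logistic fit for %s skipped: %s", var, exc)
            out[var] = {"error": str(exc)}
            continue
        table = tolerance_table(fit, config.logistic_levels)
        table.rows.to_csv(outdir / f"logistic_td_{var}.csv", index=False)
        dose_response_curve(fit).to_csv(outdir / f"logistic_curve_{var}.csv", index=False)
        binned_incidence(eligible, var).to_csv(
            outdir / f"binned_incidence_{var}.csv", index=False)
        out[var] = {
            "b0": fit.b0, "b1": fit.b1, "n_lobes": fit.n_lobes,
            "n_events": fit.n_events,
            "td": {str(r.p): {"td": r.td_gy, "se": r.se_gy}
                   for r in table.rows.itertuples()},
        }
    return out


def stage_summary(config: RunConfig, df: pd.DataFrame, outdir: Path) -> dict:
    log.info("stage 5: cohort summary")
    pat = df.groupby("patient_id")["event"].max()
    summary = baseline_table(df)
    summary.to_csv(outdir / "baseline_table.csv", index=False)
    return {
        "n_patients": int(pat.size),
        "n_lobes": int(len(df)),
        "n_patients_injured": int(pat.sum()),
        "crude_rate_pct": crude_rate(int(pat.sum()), int(pat.size)),
    }


def run(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the aggregated run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"provenance": {
        "config": config.to_jsonable(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
    }}
    stages = (("cohort", stage_cohort), ("selection", stage_select),
              ("cox", stage_cox), ("logistic", stage_logistic),
              ("summary", stage_summary))
    df = None
    for name, fn in stages:
        try:
            result = fn(config, outdir) if name == "cohort" else fn(config, df, outdir)
        except Exception:
            log.error("stage %r failed; partial artifacts kept in %s", name, outdir)
            raise
        if name == "cohort":
            df = result
        else:
            report[name] = result
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
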