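"""The per-lobe analysis record and the cohort CSV schema.

The analysis unit is one temporal lobe.  Both lobes of a patient appear as
separate rows and are treated as independently at risk given their own dose
(the bilateral-independence assumption); follow-up, death and repeat-RT
censoring act at the patient level and are shared by both rows.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .dvh import DoseMetrics

SIDES = ("left", "right")
SEXES = ("male", "female")
T_STAGES = ("T1-2", "T3-4")
CHEMO = ("yes", "no")
CENSOR_REASONS = ("alive_no_injury", "death", "repeat_rt", "end_of_followup")

#: cohort CSV column order (one row per lobe)
COHORT_COLUMNS = (
    "patient_id", "side", "time_months", "event", "censor_reason",
    "age", "sex", "t_stage", "chemo",
) + DoseMetrics.COLUMNS


class CohortFormatError(ValueError):
    """Raised with the collected list of per-row problems in a cohort CSV."""


@dataclass(frozen=True)
class LobeRecord:
    """One temporal lobe: dose metrics, clinical covariates and outcome.

    ``time`` is months from radiotherapy completion to injury (``event`` True)
    or censoring; for events the latency and the ``censor_reason`` is None.
    """

    patient_id: str
    side: str
    metrics: DoseMetrics
    age: float
    sex: str
    t_stage: str
    chemo: str
    time: float
    event: bool
    censor_reason: str | None = None

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.side not in SIDES:
            raise ValueError(f"bad side {self.side!r}")
        if self.event and self.censor_reason is not None:
            raise ValueError("an injured lobe carries no censor reason")
        if not self.event and self.censor_reason not in CENSOR_REASONS:
            raise ValueError(f"bad censor_reason {self.censor_reason!r}")

    def as_row(self) -> dict:
        row = {
            "patient_id": self.patient_id,
            "side": self.side,
            "time_months": self.time,
            "event": int(self.event),
            "censor_reason": self.censor_reason or "",
            "age": self.age,
            "sex": self.sex,
            "t_stage": self.t_stage,
            "chemo": self.chemo,
        }
        row.update(self.metrics.as_dict())
        return row


def cohort_to_frame(lobes: list[LobeRecord]) -> pd.DataFrame:
    """Tabulate records into the canonical cohort DataFrame (schema order)."""
    df = pd.DataFrame([lb.as_row() for lb in lobes], columns=list(COHORT_COLUMNS))
    return df


def _record_from_row(idx, row) -> LobeRecord:
    metrics_kwargs = {
        ("d_0_1cc" if c == "d_0.1cc" else c): float(row[c]) for c in DoseMetrics.COLUMNS
    }
    reason = row["censor_reason"]
    if pd.isna(reason) or reason == "":
        reason = None
    return LobeRecord(
        patient_id=str(row["patient_id"]),
        side=str(row["side"]),
        metrics=DoseMetrics(**metrics_kwargs),
        age=float(row["age"]),
        sex=str(row["sex"]),
        t_stage=str(row["t_stage"]),
        chemo=str(row["chemo"]),
        time=float(row["time_months"]),
        event=bool(int(row["event"])),
        censor_reason=reason,
    )


def read_cohort(path: str | Path) -> list[LobeRecord]:
    """Read and validate a per-lobe cohort CSV.

    All row-level problems are collected and reported together, with row
    numbers (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing columns {missing}")
    records, errors = [], []
    for idx, row in df.iterrows():
        try:
            records.append(_record_from_row(idx, row))
        except (ValueError, KeyError) as exc:
            errors.append(f"row {idx + 1}: {exc}")
    if errors:
        raise CohortFormatError(f"{path}: {len(errors)} bad row(s):\n" + "\n".join(errors))
    return records


def write_cohort(lobes: list[LobeRecord], path: str | Path) -> None:
    """Write records to the CSV schema read back losslessly by read_cohort."""
    cohort_to_frame(lobes).to_csv(path, index=False, float_format="%.17g")


def frame_from_records_or_frame(lobes) -> pd.DataFrame:
    """Accept either a record list or an already-tabulated cohort frame."""
    if isinstance(lobes, pd.DataFrame):
        return lobes
    return cohort_to_frame(list(lobes))
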