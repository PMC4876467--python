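"""Cumulative dose-volume histograms and the standard dosimetric scalars.

A cumulative DVH gives, for every dose level ``d``, the absolute structure
volume (cc) receiving at least ``d`` Gy.  From it we derive the 15 scalars
conventionally reported for a temporal lobe: structure volume (TLV), mean and
median dose, the maximum point dose ``D_max``, the hottest-volume doses
``D_xcc`` for x in {0.1, 1, 5, 10, 20} cc, and the absolute volumes ``V_x``
receiving at least x Gy for x in {40, 50, 60, 65, 70, 75}.

All volumes are absolute (cc), all doses physical (Gy); no fractionation
(EQD2/LQ) conversion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

D_CC_LEVELS = (0.1, 1.0, 5.0, 10.0, 20.0)
V_GY_LEVELS = (40.0, 50.0, 60.0, 65.0, 70.0, 75.0)


class DVHFormatError(ValueError):
    """Raised when a DVH table violates the cumulative-curve invariants."""


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume curve for one anatomical structure.

    ``doses`` are strictly increasing (Gy); ``volumes`` are non-increasing
    (cc), with ``volumes[0]`` the total structure volume.  The convention is
    cumulative: ``volumes[i]`` is the volume receiving at least ``doses[i]``.
    Differential DVHs are not accepted.
    """

    structure_id: str
    doses: np.ndarray
    volumes: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if d.ndim != 1 or v.ndim != 1 or d.size != v.size or d.size < 1:
            raise DVHFormatError("dose and volume columns must be equal-length 1-D arrays")
        if not np.all(np.isfinite(d)) or not np.all(np.isfinite(v)):
            raise DVHFormatError("non-finite value in DVH table")
        if d.size > 1 and not np.all(np.diff(d) > 0):
            raise DVHFormatError("dose not increasing")
        if np.any(v < 0):
            raise DVHFormatError("negative volume in DVH table")
        if d.size > 1 and np.any(np.diff(v) > 1e-12):
            raise DVHFormatError("volume not non-increasing (not a cumulative DVH)")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "volumes", v)

    @property
    def tlv(self) -> float:
        """Total structure volume in cc (volume at the lowest dose point)."""
        return float(self.volumes[0])

    @property
    def d_max(self) -> float:
        """Maximum point dose: the largest dose coordinate of the curve."""
        return float(self.doses[-1])

    def __len__(self) -> int:
        return int(self.doses.size)


@dataclass(frozen=True)
class DoseMetrics:
    """The 15 DVH-derived scalars for one lobe (doses Gy, volumes cc)."""

    tlv: float
    d_max: float
    mean_dose: float
    median_dose: float
    d_0_1cc: float
    d_1cc: float
    d_5cc: float
    d_10cc: float
    d_20cc: float
    v_40: float
    v_50: float
    v_60: float
    v_65: float
    v_70: float
    v_75: float

    #: canonical column names used in cohort tables, in schema order
    COLUMNS = (
        "d_max", "mean_dose", "median_dose", "d_0.1cc", "d_1cc", "d_5cc",
        "d_10cc", "d_20cc", "tlv", "v_40", "v_50", "v_60", "v_65", "v_70",
        "v_75",
    )

    def as_dict(self) -> dict[str, float]:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["d_0.1cc"] = out.pop("d_0_1cc")
        return {k: out[k] for k in self.COLUMNS}


def read_dvh(path: str | Path, structure_id: str | None = None) -> DVHCurve:
    """Read one cumulative DVH from a two-column CSV (header dose_gy,volume_cc)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [c.strip().lower() for c in df.columns]
    if len(cols) < 2 or cols[0] != "dose_gy" or cols[1] != "volume_cc":
        raise DVHFormatError(f"{path}: expected header 'dose_gy,volume_cc', got {list(df.columns)}")
    try:
        doses = df.iloc[:, 0].astype(float).to_numpy()
        volumes = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise DVHFormatError(f"{path}: non-numeric entry in DVH table") from exc
    return DVHCurve(structure_id or path.stem, doses, volumes)


def write_dvh(curve: DVHCurve, path: str | Path) -> None:
    """Write a curve to the CSV format read back by :func:`read_dvh`.

    Uses full float precision so the round-trip is bit-identical.
    """
    df = pd.DataFrame({"dose_gy": curve.doses, "volume_cc": curve.volumes})
    df.to_csv(path, index=False, float_format="%.17g")


def dose_at_volume(curve: DVHCurve, x: float) -> float:
    """Dose D (Gy) such that the volume receiving >= D equals ``x`` cc.

    Linear interpolation between bracketing points.  ``x = 0`` (or any x at
    or below the smallest tabulated volume) returns the maximum point dose.
    Within flat (tied-volume) segments the largest dose of the segment is
    returned.
    """
    if x < 0 or x > curve.tlv + 1e-12:
        raise ValueError(f"requested volume {x} cc outside [0, {curve.tlv}] cc")
    v = curve.volumes
    d = curve.doses
    if x <= v[-1]:
        return curve.d_max
    # volumes are non-increasing; reverse for searchsorted (ascending)
    vr = v[::-1]
    dr = d[::-1]
    # rightmost position where vr >= x when scanned in original order:
    # find first index in reversed arrays with vr >= x
    j = int(np.searchsorted(vr, x, side="left"))
    if vr[j] == x:
        # reversed doses are decreasing, so the first occurrence is the
        # largest dose of a flat (tied-volume) segment
        return float(dr[j])
    # x lies strictly between vr[j-1] and vr[j]; interpolate in dose
    v_lo, v_hi = vr[j - 1], vr[j]
    d_lo, d_hi = dr[j - 1], dr[j]
    frac = (x - v_lo) / (v_hi - v_lo)
    return float(d_lo + frac * (d_hi - d_lo))


def volume_at_dose(curve: DVHCurve, dose: float) -> float:
    """Volume (cc) receiving at least ``dose`` Gy, by linear interpolation.

    Doses beyond the last curve point return 0; doses below the first point
    return the total structure volume.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if dose > curve.d_max:
        return 0.0
    if dose <= curve.doses[0]:
        return curve.tlv
    return float(np.interp(dose, curve.doses, curve.volumes))


def summarize(curve: DVHCurve) -> DoseMetrics:
    """Compute all 15 dosimetric scalars for one cumulative DVH.

    mean dose is (1/TLV) * integral of V(d) dd by the trapezoid rule over the
    tabulated curve; median dose is the inverse-DVH lookup at TLV/2.  D_xcc
    levels above the structure volume fall back to the lowest tabulated dose.
    """
    tlv = curve.tlv
    if tlv <= 0:
        raise ValueError(f"degenerate structure {curve.structure_id!r}: zero volume")
    if len(curve) > 1:
        mean_dose = float(np.trapezoid(curve.volumes, curve.doses)) / tlv + float(curve.doses[0])
    else:
        mean_dose = float(curve.doses[0])
    d_cc = {x: dose_at_volume(curve, min(x, tlv)) for x in D_CC_LEVELS}
    v_gy = {x: volume_at_dose(curve, x) for x in V_GY_LEVELS}
    return DoseMetrics(
        tlv=tlv,
        d_max=curve.d_max,
        mean_dose=mean_dose,
        median_dose=dose_at_volume(curve, tlv / 2.0),
        d_0_1cc=d_cc[0.1],
        d_1cc=d_cc[1.0],
        d_5cc=d_cc[5.0],
        d_10cc=d_cc[10.0],
        d_20cc=d_cc[20.0],
        v_40=v_gy[40.0],
        v_50=v_gy[50.0],
        v_60=v_gy[60.0],
        v_65=v_gy[65.0],
        v_70=v_gy[70.0],
        v_75=v_gy[75.0],
    )
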