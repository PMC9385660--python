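"""Ratiometric lysosomal pH calibration from dual-emission plate readings.

Calibration wells are measured with lysosomal pH clamped to buffers of known
pH (nigericin/monensin); the emission ratio I440/I540 versus buffer pH gives
a per-experiment calibration curve, through which sample-well ratios are
inverse-mapped to absolute pH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class PlateReading:
    """One well of a dual-emission plate read (ex 329/em 440, ex 380/em 540)."""

    well: str
    role: str  # "calibration" | "sample"
    buffer_ph: float | None
    i440: float
    i540: float
    group: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("calibration", "sample"):
            raise ValueError(f"unknown well role {self.role!r}")
        if self.i440 <= 0 or self.i540 <= 0:
            raise ValueError("well intensities must be > 0")
        if self.role == "calibration" and self.buffer_ph is None:
            raise ValueError("calibration wells must carry a buffer pH")
        if self.role == "sample" and self.buffer_ph is not None:
            raise ValueError("sample wells must not carry a buffer pH")


def compute_ratio(reading: PlateReading) -> float:
    """Emission intensity ratio 440 nm / 540 nm."""
    return reading.i440 / reading.i540


def _boltzmann(ph, r_min, r_max, ph_half, slope):
    return r_min + (r_max - r_min) / (1.0 + np.exp((ph - ph_half) / slope))


@dataclass
class CalibrationCurve:
    """Fitted monotone mapping between emission ratio and pH.

    ``model`` is "interp" (monotone piecewise-linear through the per-pH mean
    ratios; the default, assumption-free over a ~1 pH span) or "sigmoid"
    (Boltzmann fit).  ``increasing`` records whether ratio rises with pH,
    auto-detected from the calibration data.
    """

    model: str
    knot_ph: np.ndarray
    knot_ratio: np.ndarray
    increasing: bool
    params: tuple | None = None
    residuals: np.ndarray | None = None

    @property
    def ph_range(self) -> tuple[float, float]:
        return float(self.knot_ph[0]), float(self.knot_ph[-1])

    def ratio_at(self, ph) -> np.ndarray:
        """Forward evaluation (used for diagnostics and round-trip checks)."""
        ph = np.asarray(ph, dtype=float)
        if self.model == "sigmoid":
            return _boltzmann(ph, *self.params)
        return np.interp(ph, self.knot_ph, self.knot_ratio)


def fit_calibration(readings: list[PlateReading], model: str = "interp") -> CalibrationCurve:
    """Fit the per-experiment ratio-vs-pH calibration curve.

    Replicate ratios are averaged per buffer pH; at least 3 distinct pH
    levels are required and the mean ratios must be strictly monotone in pH.
    """
    cal = [r for r in readings if r.role == "calibration"]
    if not cal:
        raise ValueError("no calibration wells provided")
    df = pd.DataFrame({"ph": [r.buffer_ph for r in cal], "ratio": [compute_ratio(r) for r in cal]})
    means = df.groupby("ph")["ratio"].mean().sort_index()
    if len(means) < 3:
        raise ValueError(f"need >= 3 distinct calibration pH levels, got {len(means)}")
    knot_ph = means.index.to_numpy(dtype=float)
    knot_ratio = means.to_numpy(dtype=float)
    diffs = np.diff(knot_ratio)
    if np.all(diffs > 0):
        increasing = True
    elif np.all(diffs < 0):
        increasing = False
    else:
        raise ValueError(
            "mean calibration ratios are not monotone in pH; "
            f"per-pH means: {dict(zip(knot_ph, np.round(knot_ratio, 4)))}"
        )
    if model == "interp":
        curve = CalibrationCurve("interp", knot_ph, knot_ratio, increasing)
    elif model == "sigmoid":
        r_lo, r_hi = knot_ratio.min(), knot_ratio.max()
        p0 = (r_lo, r_hi, float(knot_ph.mean()), 0.4 if not increasing else -0.4)
        params, _ = curve_fit(_boltzmann, knot_ph, knot_ratio, p0=p0, maxfev=20000)
        curve = CalibrationCurve("sigmoid", knot_ph, knot_ratio, increasing, params=tuple(params))
    else:
        raise ValueError(f"unknown calibration model {model!r}")
    curve.residuals = knot_ratio - curve.ratio_at(knot_ph)
    return curve


def ratio_to_ph(curve: CalibrationCurve, ratio: float) -> tuple[float, bool]:
    """Inverse-map an emission ratio to pH.

    Returns ``(ph, extrapolated)``; ratios beyond the calibrated span are
    clamped to the boundary pH and flagged rather than refused.
    """
    if curve.model == "sigmoid":
        grid = np.linspace(*curve.ph_range, 2001)
        grid_ratio = curve.ratio_at(grid)
    else:
        grid = curve.knot_ph
        grid_ratio = curve.knot_ratio
    if not curve.increasing:
        grid, grid_ratio = grid[::-1], grid_ratio[::-1]
    lo, hi = grid_ratio[0], grid_ratio[-1]
    if ratio <= lo:
        return float(grid[0]), ratio < lo
    if ratio >= hi:
        return float(grid[-1]), ratio > hi
    return float(np.interp(ratio, grid_ratio, grid)), False


def plate_summary(readings: list[PlateReading], curve: CalibrationCurve) -> pd.DataFrame:
    """Per-condition mean pH +/- SD over sample wells.

    SD is reported as 0 with ``n = 1`` flagged for single-well groups;
    ``n_extrapolated`` counts wells whose ratio fell outside the calibrated
    span.
    """
    rows = []
    for r in readings:
        if r.role != "sample":
            continue
        ph, flag = ratio_to_ph(curve, compute_ratio(r))
        rows.append({"well": r.well, "group": r.group, "ph": ph, "extrapolated": flag})
    if not rows:
        raise ValueError("no sample wells to summarize")
    per_well = pd.DataFrame(rows)
    summary = (
        per_well.groupby("group")
        .agg(
            mean_ph=("ph", "mean"),
            sd_ph=("ph", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0),
            n=("ph", "size"),
            n_extrapolated=("extrapolated", "sum"),
        )
        .reset_index()
    )
    summary["single_well"] = summary["n"] == 1
    return summary
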