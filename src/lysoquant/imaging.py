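"""Per-organelle quantification of multi-channel fluorescence fields.

The quantification pipeline mirrors common particle-analysis practice:
background subtraction, Gaussian blur, global threshold and connected-
component analysis define lysosomal regions of interest (ROIs) on the
organelle-marker channel; probe intensities are then measured inside those
ROIs.  The "active lysosome" readout propagates an automatic threshold
computed on a positive-control (reference) condition to all conditions of
the same experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, restoration


@dataclass
class MultiChannelField:
    """One microscopy field of view: named 2-D channels on a common raster."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.2
    field_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        for name, ch in self.channels.items():
            if np.any(ch < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            )
        return self.channels[name]


@dataclass
class SegmentationParams:
    """Parameters of the ROI-identification pipeline.

    ``background_method`` is "percentile" (per-field constant at the given
    percentile; default 20) or "rolling_ball" (radius in px).  Areas are in
    px²; blur is the Gaussian sigma in px.
    """

    background_method: str = "percentile"
    background_param: float = 20.0
    blur_sigma: float = 1.0
    threshold_method: str = "otsu"
    min_area: int = 4
    max_area: int = 2000

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")


@dataclass
class QuenchCurve:
    """Time course of mean lysosomal probe intensity, normalized to t0."""

    times_min: np.ndarray
    normalized_intensity: np.ndarray
    initial_rate_per_min: float | None = None


@dataclass
class FieldSummary:
    nuclei_count: int
    mean_cellular_fluorescence: float
    active_area_percent: float | None = None
    manders_m1: float | None = None
    manders_m2: float | None = None


def subtract_background(
    raster: np.ndarray, method: str = "percentile", parameter: float = 20.0
) -> np.ndarray:
    """Estimate and subtract background, clamping the result at zero.

    "percentile" subtracts a per-field constant (the given percentile of all
    pixels); "rolling_ball" subtracts a morphological rolling-ball estimate
    with the given radius.
    """
    raster = np.asarray(raster, dtype=float)
    if method == "percentile":
        if not 0 < parameter < 100:
            raise ValueError("percentile must be in (0, 100)")
        bg = np.percentile(raster, parameter)
    elif method == "rolling_ball":
        if parameter <= 0:
            raise ValueError("rolling-ball radius must be > 0")
        bg = restoration.rolling_ball(raster, radius=parameter)
    else:
        raise ValueError(f"unknown background method {method!r}")
    return np.maximum(raster - bg, 0.0)


def _global_threshold(raster: np.ndarray, method: str) -> float | None:
    """Threshold a background-subtracted raster; None for a constant image."""
    if np.ptp(raster) == 0:
        return None
    if method == "otsu":
        return float(filters.threshold_otsu(raster))
    if method == "isodata":
        return isodata_threshold(raster.ravel())
    raise ValueError(f"unknown threshold method {method!r}")


def segment_lysosomes(
    field: MultiChannelField,
    params: SegmentationParams | None = None,
    marker_channel: str = "marker",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Identify lysosomal ROIs on the marker channel.

    Returns the label map (0 = background) and a geometry-only organelle
    table (label, area in px² and µm², centroid).  Pixels equal to the
    threshold count as background.
    """
    params = params or SegmentationParams()
    raster = field.channel(marker_channel)
    work = subtract_background(raster, params.background_method, params.background_param)
    if params.blur_sigma > 0:
        work = ndimage.gaussian_filter(work, params.blur_sigma)
    thr = _global_threshold(work, params.threshold_method)
    if thr is None:
        labels = np.zeros(field.shape, dtype=np.int32)
    else:
        labels = measure.label(work > thr, connectivity=2).astype(np.int32)
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    next_id = 1
    for prop in measure.regionprops(labels):
        if params.min_area <= prop.area <= params.max_area:
            keep[prop.label] = next_id
            rows.append(
                {
                    "label": next_id,
                    "area_px2": int(prop.area),
                    "area_um2": prop.area * field.pixel_size_um**2,
                    "centroid_row": prop.centroid[0],
                    "centroid_col": prop.centroid[1],
                }
            )
            next_id += 1
    labels = keep[labels]
    table = pd.DataFrame(
        rows, columns=["label", "area_px2", "area_um2", "centroid_row", "centroid_col"]
    )
    return labels, table


def count_nuclei(
    field: MultiChannelField,
    nuclei_channel: str = "nuclei",
    blur_sigma: float = 4.0,
    min_area: int = 200,
    max_area: int = 20000,
) -> int:
    """Count nuclei as nucleus-scale connected components of the Hoechst channel.

    Nuclei closer than about one radius merge into a single component and are
    counted once; this under-count is the documented proxy for cell number.
    """
    raster = subtract_background(field.channel(nuclei_channel))
    work = ndimage.gaussian_filter(raster, blur_sigma)
    thr = _global_threshold(work, "otsu")
    if thr is None:
        return 0
    labels = measure.label(work > thr, connectivity=2)
    count = 0
    for prop in measure.regionprops(labels):
        if min_area <= prop.area <= max_area:
            count += 1
    return count


def measure_rois(
    field: MultiChannelField,
    labels: np.ndarray,
    channels: list[str],
    background_method: str = "percentile",
    background_param: float = 20.0,
) -> pd.DataFrame:
    """Integrated density per ROI: sum of background-subtracted pixel values.

    Returns one row per label with area and ``intden_<channel>`` columns plus
    ``recruitment_<channel>`` = integrated density / ROI area (the per-
    particle normalization used for V1-subunit recruitment to marker-defined
    lysosomes).
    """
    ids = np.arange(1, labels.max() + 1)
    areas = ndimage.sum_labels(np.ones_like(labels, dtype=float), labels, ids)
    table = pd.DataFrame({"label": ids, "area_px2": areas.astype(int)})
    for name in channels:
        raster = subtract_background(field.channel(name), background_method, background_param)
        sums = ndimage.sum_labels(raster, labels, ids)
        table[f"intden_{name}"] = sums
        table[f"recruitment_{name}"] = sums / areas
    return table


def mean_cellular_fluorescence(table: pd.DataFrame, nuclei_count: int, channel: str) -> float:
    """Total probe integrated density over all ROIs, per nucleus."""
    if nuclei_count <= 0:
        raise ValueError("nuclei_count must be > 0")
    return float(table[f"intden_{channel}"].sum()) / nuclei_count


def normalize_to_control(values, control_mask) -> np.ndarray:
    """Divide every value by the control-group mean (control mean becomes 1)."""
    values = np.asarray(values, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    if not control_mask.any():
        raise ValueError("control group is empty")
    return values / values[control_mask].mean()


def manders_coefficients(
    ch1: np.ndarray, ch2: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Mander's colocalization coefficients of two background-subtracted rasters.

    M1 is the fraction of channel-1 intensity in pixels where channel 2 is
    positive; M2 symmetrically.  Both lie in [0, 1].
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("rasters must share one shape")
    if mask is not None:
        ch1 = np.where(mask, ch1, 0.0)
        ch2 = np.where(mask, ch2, 0.0)
    tot1, tot2 = ch1.sum(), ch2.sum()
    if tot1 == 0 or tot2 == 0:
        raise ValueError("a channel with zero total intensity has undefined coefficients")
    m1 = ch1[ch2 > 0].sum() / tot1
    m2 = ch2[ch1 > 0].sum() / tot2
    return float(m1), float(m2)


def isodata_threshold(values: np.ndarray) -> float:
    """Iterative intermeans (IsoData) threshold of a 1-D sample.

    Repeats t <- (mean below t + mean above t) / 2 from the sample mean until
    convergence.  A constant sample returns that constant (degenerate case;
    with ties counted as below, nothing then exceeds the threshold).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot threshold an empty sample")
    if np.ptp(values) == 0:
        return float(values[0])
    t = values.mean()
    for _ in range(500):
        lo = values[values <= t]
        hi = values[values > t]
        if hi.size == 0 or lo.size == 0:
            break
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < 1e-9:
            t = t_new
            break
        t = t_new
    return float(t)


def reference_auto_threshold(
    fields: list[MultiChannelField],
    probe_channel: str = "probe",
    marker_channel: str = "marker",
    params: SegmentationParams | None = None,
    background_method: str = "percentile",
    background_param: float = 20.0,
) -> float:
    """Average per-field auto-threshold of the probe signal in lysosomal ROIs.

    Computed on the reference (positive control) condition and then
    propagated to all conditions of the same experiment.
    """
    if not fields:
        raise ValueError("need at least one reference field")
    per_field = []
    for f in fields:
        labels, _ = segment_lysosomes(f, params, marker_channel)
        probe = subtract_background(f.channel(probe_channel), background_method, background_param)
        roi_values = probe[labels > 0]
        if roi_values.size == 0:
            continue
        per_field.append(isodata_threshold(roi_values))
    if not per_field:
        raise ValueError("no lysosomal ROIs found in any reference field")
    return float(np.mean(per_field))


@dataclass
class ActiveFractionResult:
    area_percent: float
    organelle_percent: float
    per_organelle_active: pd.Series
    threshold: float


def active_fraction(
    field: MultiChannelField,
    labels: np.ndarray,
    threshold: float,
    probe_channel: str = "probe",
    background_method: str = "percentile",
    background_param: float = 20.0,
    organelle_rule_fraction: float = 0.5,
) -> ActiveFractionResult:
    """Share of lysosomal area (and of organelles) with probe above threshold.

    ``area_percent`` is 100 x (ROI pixels with probe > threshold) / (all ROI
    pixels).  An organelle counts as active when more than
    ``organelle_rule_fraction`` of its pixels exceed the threshold; pixels
    equal to the threshold count as below.
    """
    probe = subtract_background(field.channel(probe_channel), background_method, background_param)
    roi = labels > 0
    total = int(roi.sum())
    if total == 0:
        return ActiveFractionResult(0.0, 0.0, pd.Series(dtype=bool), threshold)
    above = probe > threshold
    area_percent = 100.0 * (above & roi).sum() / total
    ids = np.arange(1, labels.max() + 1)
    areas = ndimage.sum_labels(roi.astype(float), labels, ids)
    hot = ndimage.sum_labels(above.astype(float), labels, ids)
    flags = pd.Series(hot / areas > organelle_rule_fraction, index=ids, name="active")
    organelle_percent = 100.0 * flags.mean() if len(flags) else 0.0
    return ActiveFractionResult(float(area_percent), float(organelle_percent), flags, threshold)


def recruitment_summary(tables: list[pd.DataFrame], channel: str) -> dict:
    """Pool per-organelle recruitment values across fields.

    Returns median, 25th/75th percentiles and a relative-frequency histogram
    of probe integrated density normalized to marker-defined particle area.
    """
    col = f"recruitment_{channel}"
    pooled = np.concatenate([np.asarray(t[col], dtype=float) for t in tables])
    if pooled.size == 0:
        raise ValueError("no organelles to summarize")
    q25, med, q75 = np.percentile(pooled, [25, 50, 75])
    counts, edges = np.histogram(pooled, bins=30)
    return {
        "n_organelles": int(pooled.size),
        "median": float(med),
        "iqr": (float(q25), float(q75)),
        "hist_density": counts / pooled.size,
        "hist_edges": edges,
    }


def quench_timecourse(
    fields: list[tuple[float, MultiChannelField]],
    probe_channel: str = "probe",
    marker_channel: str = "marker",
    params: SegmentationParams | None = None,
    roi_policy: str = "resegment",
    rate_frames: int = 3,
) -> QuenchCurve:
    """Mean lysosomal probe intensity over time, normalized to the first frame.

    ``roi_policy`` "resegment" re-identifies ROIs per frame (organelles
    move); "frozen" reuses the t0 ROIs.  The initial quench rate is minus the
    least-squares slope of the normalized curve over the first
    ``rate_frames`` frames, in fraction/min.
    """
    if len(fields) < 3:
        raise ValueError("need at least 3 time points")
    times = np.array([t for t, _ in fields], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("time vector must be strictly increasing")
    if roi_policy not in ("resegment", "frozen"):
        raise ValueError(f"unknown roi_policy {roi_policy!r}")
    frozen_labels = None
    means = []
    for _, f in fields:
        if roi_policy == "frozen":
            if frozen_labels is None:
                frozen_labels, _ = segment_lysosomes(f, params, marker_channel)
            labels = frozen_labels
        else:
            labels, _ = segment_lysosomes(f, params, marker_channel)
        probe = subtract_background(f.channel(probe_channel))
        roi = labels > 0
        means.append(probe[roi].mean() if roi.any() else 0.0)
    means = np.array(means, dtype=float)
    if means[0] == 0:
        raise ValueError("no lysosomal signal at t0; cannot normalize")
    norm = means / means[0]
    k = min(rate_frames, len(norm))
    slope = np.polyfit(times[:k], norm[:k], 1)[0]
    return QuenchCurve(times, norm, initial_rate_per_min=float(-slope))
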