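"""Seeded generators for microscopy fields, plate readings and proteomes.

Every generator returns the data alongside a :class:`GroundTruth` record of
what was planted, so downstream quantification can be tested as parameter
recovery.  Identical (preset, seed) always produces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .imaging import MultiChannelField
from .phcal import PlateReading
from .presets import ImagingPreset, PhPreset, ProteomicsPreset


class InfeasibleFieldError(ValueError):
    """Requested organelle count cannot be placed without overlap."""


@dataclass
class GroundTruth:
    """Planted objects of one generated dataset (one record per object)."""

    organelle_centers: np.ndarray | None = None
    organelle_radii: np.ndarray | None = None
    organelle_active: np.ndarray | None = None
    organelle_probe_intensity: np.ndarray | None = None
    nuclei_centers: np.ndarray | None = None
    sample_ph: float | None = None
    class_folds: dict | None = None
    classes: pd.Series | None = None
    missing_mask: pd.DataFrame | None = None
    true_log2: pd.DataFrame | None = None


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    radii: np.ndarray,
    clearance: float,
    max_attempts: int = 20000,
) -> np.ndarray:
    """Rejection-sample centers so discs keep ``clearance`` px between rims."""
    centers = np.empty((n, 2))
    placed = 0
    attempts = 0
    while placed < n:
        if attempts >= max_attempts:
            raise InfeasibleFieldError(
                f"could not place {n} organelles of this size in a "
                f"{shape[0]}x{shape[1]} field without overlap"
            )
        attempts += 1
        margin = 3.0 * radii[placed] + 2.0
        cand = np.array(
            [
                rng.uniform(margin, shape[0] - margin),
                rng.uniform(margin, shape[1] - margin),
            ]
        )
        if placed:
            d = np.linalg.norm(centers[:placed] - cand, axis=1)
            if np.any(d < radii[:placed] + radii[placed] + clearance):
                continue
        centers[placed] = cand
        placed += 1
    return centers


def _render_gaussians(
    canvas: np.ndarray,
    centers: np.ndarray,
    sigmas: np.ndarray,
    amplitudes: np.ndarray,
    power: float = 2.0,
) -> None:
    """Add radial profiles amp*exp(-(r^2/2s^2)^(power/2)) in-place.

    power=2 is a Gaussian punctum; power=4 gives the flatter-topped profile
    used for nuclei.
    """
    h, w = canvas.shape
    for (cy, cx), s, a in zip(centers, sigmas, amplitudes):
        ext = int(np.ceil(4 * s))
        y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
        x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2)
        canvas[y0:y1, x0:x1] += a * np.exp(-(r2 ** (power / 2.0)))


def make_image_field(
    preset: ImagingPreset,
    seed: int,
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.2,
) -> tuple[MultiChannelField, GroundTruth]:
    """Generate one field with channels "marker", "probe" and "nuclei".

    Organelles are diffraction-limited Gaussian puncta (sigma = radius/2) on
    a constant cytosolic background with additive Gaussian read noise; probe
    amplitude is drawn from the active or inactive distribution according to
    the preset's active fraction.
    """
    rng = np.random.default_rng(seed)
    n = preset.n_organelles_per_field
    radii = np.clip(
        rng.normal(preset.organelle_radius_px[0], preset.organelle_radius_px[1], n),
        1.5,
        None,
    )
    centers = _place_points(rng, n, shape, radii, clearance=6.0) if n else np.empty((0, 2))
    sigmas = radii / 2.0
    marker_amp = np.clip(
        rng.normal(preset.marker_intensity[0], preset.marker_intensity[1], n), 10.0, None
    )
    active = rng.random(n) < preset.probe_active_fraction
    probe_amp = np.where(
        active,
        rng.normal(preset.probe_intensity_active[0], preset.probe_intensity_active[1], n),
        rng.normal(preset.probe_intensity_inactive[0], preset.probe_intensity_inactive[1], n),
    )
    probe_amp = np.clip(probe_amp, 1.0, None)

    marker = np.full(shape, preset.cytosol_background * 0.25)
    probe = np.full(shape, float(preset.cytosol_background))
    _render_gaussians(marker, centers, sigmas, marker_amp)
    # The dequenched probe product fills the organelle lumen, so its
    # per-organelle profile is plateau-like (flat-topped) rather than a
    # diffraction-limited Gaussian point source.
    _render_gaussians(probe, centers, radii / 1.6, probe_amp, power=4.0)

    n_nuc = preset.nuclei_per_field
    nuc_radii = np.clip(rng.normal(22.0, 3.0, n_nuc), 12.0, None)
    nuc_centers = (
        _place_points(rng, n_nuc, shape, nuc_radii, clearance=8.0)
        if n_nuc
        else np.empty((0, 2))
    )
    nuclei = np.full(shape, 10.0)
    _render_gaussians(nuclei, nuc_centers, nuc_radii / 1.6, np.full(n_nuc, 400.0), power=4.0)

    channels = {}
    for name, raster in (("marker", marker), ("probe", probe), ("nuclei", nuclei)):
        noisy = raster + rng.normal(0.0, preset.noise_sd, shape)
        channels[name] = np.clip(noisy, 0.0, None)

    field = MultiChannelField(
        channels=channels,
        pixel_size_um=pixel_size_um,
        field_id=f"{preset.name}_seed{seed}",
        condition=preset.name,
    )
    truth = GroundTruth(
        organelle_centers=centers,
        organelle_radii=radii,
        organelle_active=active,
        # integral of amp*exp(-(r^2/2s^2)^2) over the plane: amp*pi^(3/2)*s^2
        organelle_probe_intensity=probe_amp * np.pi**1.5 * (radii / 1.6) ** 2,
        nuclei_centers=nuc_centers,
    )
    return field, truth


def ratio_curve(ph, params: tuple[float, float, float, float]):
    """Generating emission-ratio curve: Boltzmann sigmoid, falling with pH."""
    r_min, r_max, ph_half, slope = params
    return r_min + (r_max - r_min) / (1.0 + np.exp((np.asarray(ph, float) - ph_half) / slope))


def make_plate(
    preset: PhPreset, seed: int, n_sample_wells: int | None = None
) -> tuple[list[PlateReading], GroundTruth]:
    """Generate calibration and sample wells of one dual-emission plate.

    The observed I440/I540 ratio is the preset curve at the well's pH with
    multiplicative log-normal noise of the stated CV; I540 carries an
    independent well-scale factor that cancels in the ratio.
    """
    rng = np.random.default_rng(seed)
    if n_sample_wells is None:
        n_sample_wells = preset.replicate_count
    readings: list[PlateReading] = []
    idx = 0

    def _well(ph: float, role: str, group: str) -> PlateReading:
        nonlocal idx
        idx += 1
        true_ratio = float(ratio_curve(ph, preset.ratio_curve_params))
        noisy_ratio = true_ratio * rng.lognormal(0.0, preset.well_noise_cv)
        i540 = 5e4 * rng.lognormal(0.0, 0.1)
        return PlateReading(
            well=f"W{idx:03d}",
            role=role,
            buffer_ph=ph if role == "calibration" else None,
            i440=noisy_ratio * i540,
            i540=i540,
            group=group,
        )

    for ph in preset.calibration_phs:
        for _ in range(preset.replicate_count):
            readings.append(_well(ph, "calibration", "calibration"))
    for _ in range(n_sample_wells):
        readings.append(_well(preset.true_sample_ph, "sample", preset.name))
    return readings, GroundTruth(sample_ph=preset.true_sample_ph)


def make_proteomics(
    preset: ProteomicsPreset, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a log2 protein-group intensity matrix for "lyso" vs "PNS".

    Compartment-annotated proteins are shifted by log2(planted fold) in the
    lysosomal-fraction samples.  Entries are then deleted by an intensity-
    dependent (logistic in -intensity) rule so that low-abundance values are
    preferentially missing, at the preset's overall rate.

    Returns (matrix, design, truth); matrix rows are proteins, columns
    samples, missing entries NaN; design maps sample to condition.
    """
    if preset.n_replicates < 2:
        raise ValueError("at least 2 replicates per condition are required")
    rng = np.random.default_rng(seed)
    n = preset.n_proteins
    classes = np.array(["other"] * n, dtype=object)
    n_lyso = int(round(preset.frac_lysosomal * n))
    special = {k: int(round(v * n)) for k, v in preset.class_fractions.items()}
    pos = 0
    for cls, cnt in special.items():
        classes[pos : pos + cnt] = cls
        pos += cnt
    classes[pos : pos + n_lyso] = "lysosomal"
    order = rng.permutation(n)
    classes = pd.Series(classes[order], index=[f"P{i:05d}" for i in range(n)], name="class")

    base = rng.normal(*preset.base_log2_intensity, n)
    base[classes.values != "other"] += preset.class_base_offset
    log2_shift = np.zeros(n)
    for cls, fold in preset.planted_enrichment.items():
        log2_shift[classes.values == cls] = np.log2(fold)

    samples = [f"lyso_{i+1}" for i in range(preset.n_replicates)] + [
        f"PNS_{i+1}" for i in range(preset.n_replicates)
    ]
    conditions = ["lyso"] * preset.n_replicates + ["PNS"] * preset.n_replicates
    design = pd.DataFrame({"sample": samples, "condition": conditions})

    true_means = np.column_stack(
        [base + log2_shift if c == "lyso" else base for c in conditions]
    )
    values = true_means + rng.normal(0.0, preset.within_sd, true_means.shape)

    steep, rate = preset.missing_model
    if rate > 0:
        from scipy.optimize import brentq

        flat = values.ravel()

        def mean_p(x0: float) -> float:
            return float(np.mean(1.0 / (1.0 + np.exp(steep * (flat - x0)))))

        lo, hi = flat.min() - 50.0, flat.max() + 50.0
        x0 = brentq(lambda x: mean_p(x) - rate, lo, hi)
        p_miss = 1.0 / (1.0 + np.exp(steep * (values - x0)))
        missing = rng.random(values.shape) < p_miss
    else:
        missing = np.zeros(values.shape, dtype=bool)

    matrix = pd.DataFrame(values, index=classes.index, columns=samples)
    matrix = matrix.mask(missing)
    truth = GroundTruth(
        class_folds={**preset.planted_enrichment, "other": 1.0},
        classes=classes,
        missing_mask=pd.DataFrame(missing, index=classes.index, columns=samples),
        true_log2=pd.DataFrame(values, index=classes.index, columns=samples),
    )
    return matrix, design, truth
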