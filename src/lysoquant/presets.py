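"""Named presets encoding the study conditions for the synthetic generators.

Each preset freezes the parameters of one experimental condition: resting
(control) versus mTOR-kinase-inhibited (torin1) fibroblasts for imaging and
lysosomal pH, and the lysosomal-fraction versus whole-lysate (post-nuclear
supernatant, PNS) comparison for organelle proteomics.  Downstream modules
are tested by recovering these planted values, so the presets are part of the
package contract, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ImagingPreset:
    """Parameters for one synthetic microscopy condition.

    Intensities are arbitrary units on a 16-bit-like scale; ``(mean, sd)``
    pairs describe per-organelle draws.  ``probe_active_fraction`` is the
    planted fraction of lysosomes with high protease (probe) activity.
    """

    name: str
    n_organelles_per_field: int
    organelle_radius_px: tuple[float, float]
    marker_intensity: tuple[float, float]
    probe_active_fraction: float
    probe_intensity_active: tuple[float, float]
    probe_intensity_inactive: tuple[float, float]
    cytosol_background: float
    nuclei_per_field: int
    noise_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probe_active_fraction <= 1.0:
            raise ValueError("probe_active_fraction must be in [0, 1]")
        if self.probe_intensity_active[0] <= self.probe_intensity_inactive[0]:
            raise ValueError("active probe intensity mean must exceed inactive mean")
        for pair in (
            self.organelle_radius_px,
            self.marker_intensity,
            self.probe_intensity_active,
            self.probe_intensity_inactive,
        ):
            if pair[1] < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.n_organelles_per_field < 0 or self.nuclei_per_field < 0:
            raise ValueError("object counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PhPreset:
    """Parameters for one synthetic dual-emission plate experiment.

    ``ratio_curve_params`` are the Boltzmann sigmoid parameters
    ``(r_min, r_max, ph_half, slope)`` of the generating emission-ratio
    curve ratio(pH); the ratio falls monotonically with rising pH.
    """

    name: str
    true_sample_ph: float
    calibration_phs: tuple[float, ...]
    ratio_curve_params: tuple[float, float, float, float]
    well_noise_cv: float
    replicate_count: int

    def __post_init__(self) -> None:
        phs = self.calibration_phs
        if any(b <= a for a, b in zip(phs, phs[1:])):
            raise ValueError("calibration_phs must be strictly increasing")
        if not phs[0] <= self.true_sample_ph <= phs[-1]:
            raise ValueError("true_sample_ph must lie within the calibration range")
        if self.well_noise_cv < 0:
            raise ValueError("well_noise_cv must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


@dataclass(frozen=True)
class ProteomicsPreset:
    """Parameters for one synthetic protein-group intensity matrix.

    ``planted_enrichment`` maps compartment class to the fold by which that
    class is enriched in the lysosomal fraction over the whole lysate;
    proteins of class "other" define the non-lysosomal background (fold 1).
    ``missing_model`` is ``(steepness, overall_rate)`` of the
    intensity-dependent (missing-not-at-random) deletion rule.
    """

    name: str
    n_proteins: int
    frac_lysosomal: float
    planted_enrichment: dict = field(
        default_factory=lambda: {"lysosomal": 45.0, "V-ATPase": 62.0, "mTORC1": 80.0}
    )
    class_fractions: dict = field(
        default_factory=lambda: {"V-ATPase": 0.01, "mTORC1": 0.005}
    )
    n_replicates: int = 5
    base_log2_intensity: tuple[float, float] = (25.0, 2.0)
    # Annotated compartment classes emulate abundant, consistently quantified
    # complexes: their base intensity is offset above the bulk so their
    # lysate values sit clear of the censoring (MNAR) tail.
    class_base_offset: float = 1.5
    within_sd: float = 0.25
    missing_model: tuple[float, float] = (2.0, 0.08)
    condition_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.planted_enrichment.values()):
            raise ValueError("planted enrichment folds must be > 0")
        rate = self.missing_model[1]
        if not 0.0 <= rate < 1.0:
            raise ValueError("overall missing rate must be in [0, 1)")
        if self.n_replicates < 2:
            raise ValueError("at least 2 replicates per condition are required")
        if not 0.0 < self.frac_lysosomal < 1.0:
            raise ValueError("frac_lysosomal must be in (0, 1)")


# Control fibroblasts: <20% of lysosomes show discernible cathepsin activity.
# Torin1-treated: ~60% show strong probe fluorescence.  Organelle geometry and
# intensity scales are free parameters chosen for realistic puncta on a
# diffuse cytosolic background (see docs/methods.md).
IMAGING_PRESETS: dict[str, ImagingPreset] = {
    "control": ImagingPreset(
        name="control",
        n_organelles_per_field=120,
        organelle_radius_px=(4.0, 0.8),
        marker_intensity=(600.0, 120.0),
        probe_active_fraction=0.18,
        probe_intensity_active=(900.0, 150.0),
        probe_intensity_inactive=(80.0, 25.0),
        cytosol_background=40.0,
        nuclei_per_field=10,
        noise_sd=8.0,
    ),
    "torin1": ImagingPreset(
        name="torin1",
        n_organelles_per_field=120,
        organelle_radius_px=(4.0, 0.8),
        marker_intensity=(600.0, 120.0),
        probe_active_fraction=0.60,
        probe_intensity_active=(900.0, 150.0),
        probe_intensity_inactive=(80.0, 25.0),
        cytosol_background=40.0,
        nuclei_per_field=10,
        noise_sd=8.0,
    ),
}

_CAL_PHS = (4.2, 4.4, 4.6, 4.8, 5.0, 5.2)
# Boltzmann (r_min, r_max, ph_half, slope): ratio ~3x fall over pH 4.2-5.2,
# emulating the steep ratiometric response of the probe around its pKa.
_RATIO_PARAMS = (0.15, 2.5, 4.7, 0.42)

PH_PRESETS: dict[str, PhPreset] = {
    "mef_control": PhPreset(
        name="mef_control",
        true_sample_ph=4.7,
        calibration_phs=_CAL_PHS,
        ratio_curve_params=_RATIO_PARAMS,
        well_noise_cv=0.05,
        replicate_count=3,
    ),
    "mef_torin1": PhPreset(
        name="mef_torin1",
        true_sample_ph=4.5,
        calibration_phs=_CAL_PHS,
        ratio_curve_params=_RATIO_PARAMS,
        well_noise_cv=0.05,
        replicate_count=3,
    ),
}

PROTEOMICS_PRESETS: dict[str, ProteomicsPreset] = {
    "default": ProteomicsPreset(
        name="default",
        n_proteins=2000,
        frac_lysosomal=0.10,
        n_replicates=5,
    ),
}
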