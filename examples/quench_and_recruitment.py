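"""Time-resolved quenching and per-organelle recruitment summaries.

Builds a synthetic FITC-quenching time course (probe fluorescence decaying
as lysosomes re-acidify after washout of a V-ATPase inhibitor) and a
recruitment comparison (probe integrated density per unit marker area,
the per-particle measure used for V1-subunit recruitment to lysosomes).
"""

import numpy as np

from lysoquant import (
    IMAGING_PRESETS,
    MultiChannelField,
    make_image_field,
    measure_rois,
    quench_timecourse,
    recruitment_summary,
    segment_lysosomes,
)
from lysoquant.synthdata import _render_gaussians

# --- quench time course: probe amplitude decays at 0.12 / min ---------------
rng = np.random.default_rng(1)
marker = np.full((256, 256), 10.0)
centers = rng.uniform(30, 226, (12, 2))
_render_gaussians(marker, centers, np.full(12, 2.0), np.full(12, 500.0))
frames = []
for t in (0.0, 0.5, 1.0, 1.5, 2.0, 4.0, 8.0):
    probe = np.full((256, 256), 40.0)
    _render_gaussians(probe, centers, np.full(12, 2.5),
                      np.full(12, 800.0 * np.exp(-0.12 * t)), power=4.0)
    frames.append((t, MultiChannelField(channels={"marker": marker, "probe": probe})))

curve = quench_timecourse(frames, roi_policy="frozen")
print("time (min):", curve.times_min.tolist())
print("normalized lysosomal FITC:", [round(float(v), 3) for v in curve.normalized_intensity])
print(f"initial quench rate: {curve.initial_rate_per_min:.3f} /min (planted 0.12)")

# --- recruitment: probe density per marker-defined particle -----------------
print()
for name in ("control", "torin1"):
    tables = []
    for seed in (1, 2, 3):
        field, _ = make_image_field(IMAGING_PRESETS[name], seed)
        labels, _ = segment_lysosomes(field)
        tables.append(measure_rois(field, labels, ["probe"]))
    s = recruitment_summary(tables, "probe")
    print(f"{name}: median recruitment {s['median']:.0f} a.u./px^2 "
          f"(IQR {s['iqr'][0]:.0f}-{s['iqr'][1]:.0f}, n={s['n_organelles']} organelles)")

print(
    "\nThe quench rate reads out V-ATPase proton pumping; the recruitment "
    "median rises when more organelles carry high probe signal."
)
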