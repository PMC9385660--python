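"""Recover absolute lysosomal pH from a dual-emission plate read.

Generates one synthetic plate per condition (calibration wells at six
buffer pH levels from 4.2 to 5.2 plus three sample wells), fits the
per-experiment ratio-vs-pH calibration curve and inverse-maps the sample
ratios to pH.
"""

from lysoquant import PH_PRESETS, fit_calibration, make_plate, plate_summary

for preset_name in ("mef_control", "mef_torin1"):
    preset = PH_PRESETS[preset_name]
    readings, truth = make_plate(preset, seed=1)
    curve = fit_calibration(readings)
    summary = plate_summary(readings, curve)
    row = summary.loc[summary["group"] == preset_name].iloc[0]
    print(
        f"{preset_name}: recovered pH {row['mean_ph']:.2f} +/- {row['sd_ph']:.2f} "
        f"(n={row['n']} wells, true pH {truth.sample_ph})"
    )

print(
    "\nResting lysosomes sit near pH 4.7; one hour of mTOR-kinase inhibition "
    "acidifies them to ~pH 4.5, the shift that activates luminal proteases."
)
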