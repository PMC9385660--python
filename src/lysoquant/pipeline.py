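"""Desk-scale orchestration: simulate -> quantify -> report.

The recovery functions here run each analysis stage end-to-end against the
synthetic generators and compare the recovered quantities with the planted
preset truths; :func:`reproduce` wires them into a fully seeded, file-backed
run whose outputs are byte-identical across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .imaging import (
    SegmentationParams,
    active_fraction,
    reference_auto_threshold,
    segment_lysosomes,
)
from .phcal import fit_calibration, plate_summary
from .presets import IMAGING_PRESETS, PH_PRESETS, PROTEOMICS_PRESETS
from .protstats import (
    ImputationParams,
    class_enrichment,
    filter_valid,
    impute,
    quantile_normalize,
)
from .synthdata import make_image_field, make_plate, make_proteomics


def ph_recovery(preset_name: str, seed: int, model: str = "interp") -> dict:
    """Generate one plate and recover the sample-group mean pH."""
    preset = PH_PRESETS[preset_name]
    readings, truth = make_plate(preset, seed)
    curve = fit_calibration(readings, model=model)
    summary = plate_summary(readings, curve)
    row = summary.loc[summary["group"] == preset.name].iloc[0]
    return {
        "preset": preset_name,
        "true_ph": truth.sample_ph,
        "mean_ph": float(row["mean_ph"]),
        "sd_ph": float(row["sd_ph"]),
        "n_wells": int(row["n"]),
    }


def active_fraction_recovery(
    seed: int,
    n_fields: int = 20,
    control_preset: str = "control",
    reference_preset: str = "torin1",
    params: SegmentationParams | None = None,
) -> dict:
    """Score per-organelle cathepsin activity with a propagated auto-threshold.

    Generates ``n_fields`` fields per condition (seeds seed..seed+n-1),
    derives the IsoData auto-threshold from the reference (torin1) fields,
    and pools the per-organelle active calls per condition.
    """
    params = params or SegmentationParams()
    conditions = {
        control_preset: [
            make_image_field(IMAGING_PRESETS[control_preset], seed + i)
            for i in range(n_fields)
        ],
        reference_preset: [
            make_image_field(IMAGING_PRESETS[reference_preset], seed + i)
            for i in range(n_fields)
        ],
    }
    threshold = reference_auto_threshold(
        [f for f, _ in conditions[reference_preset]], params=params
    )
    out: dict = {"threshold": threshold, "n_fields": n_fields, "conditions": {}}
    for name, pairs in conditions.items():
        n_active = n_total = n_planted = n_true_active = 0
        area_percents = []
        for field, truth in pairs:
            labels, _ = segment_lysosomes(field, params)
            res = active_fraction(field, labels, threshold)
            n_active += int(res.per_organelle_active.sum())
            n_total += len(res.per_organelle_active)
            area_percents.append(res.area_percent)
            n_planted += len(truth.organelle_active)
            n_true_active += int(truth.organelle_active.sum())
        out["conditions"][name] = {
            "active_percent": 100.0 * n_active / n_total if n_total else 0.0,
            "mean_area_percent": float(np.mean(area_percents)),
            "n_detected": n_total,
            "n_planted": n_planted,
            "true_active_percent": 100.0 * n_true_active / n_planted if n_planted else 0.0,
        }
    return out


def enrichment_recovery(
    seed: int,
    preset_name: str = "default",
    imputation_seed: int | None = None,
) -> dict:
    """Run filter -> group-wise quantile normalization -> imputation ->
    class enrichment on a generated matrix and report recovered class folds."""
    preset = PROTEOMICS_PRESETS[preset_name]
    matrix, design, truth = make_proteomics(preset, seed)
    filtered = filter_valid(matrix, design)
    groups = dict(zip(design["sample"], design["condition"]))
    normalized = quantile_normalize(filtered, groups=groups)
    imputed = impute(
        normalized, ImputationParams(seed=seed if imputation_seed is None else imputation_seed)
    )
    enr = class_enrichment(imputed, truth.classes, design)
    return {
        "preset": preset_name,
        "n_proteins": preset.n_proteins,
        "n_after_filter": len(filtered),
        "class_fold": enr["class_fold"],
        "planted_fold": truth.class_folds,
    }


@dataclass
class RunConfig:
    """Configuration of one reproducible desk-scale run."""

    out_dir: str | Path
    seed: int = 1
    stages: tuple[str, ...] = ("simulate", "analyze")
    assays: tuple[str, ...] = ("ph", "imaging", "proteomics")
    n_fields: int = 20
    imaging_presets: tuple[str, str] = ("control", "torin1")
    ph_presets: tuple[str, ...] = ("mef_control", "mef_torin1")
    proteomics_preset: str = "default"
    segmentation: SegmentationParams = dataclass_field(default_factory=SegmentationParams)
    write_images: bool = True

    def __post_init__(self) -> None:
        for p in self.imaging_presets:
            if p not in IMAGING_PRESETS:
                raise ValueError(f"unknown imaging preset {p!r}")
        for p in self.ph_presets:
            if p not in PH_PRESETS:
                raise ValueError(f"unknown pH preset {p!r}")
        if self.proteomics_preset not in PROTEOMICS_PRESETS:
            raise ValueError(f"unknown proteomics preset {self.proteomics_preset!r}")
        for s in self.stages:
            if s not in ("simulate", "analyze"):
                raise ValueError(f"unknown stage {s!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order and write a report.

    "simulate" writes the synthetic datasets and their ground truth;
    "analyze" runs the quantification pipelines and writes recovery tables
    plus ``report.json``.  Outputs carry seeds but no wall-clock times, so a
    repeat run with the same config is byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(config.stages), "recovered": {}}

    if "simulate" in config.stages:
        _simulate(config, out)
    if "analyze" in config.stages:
        if "simulate" not in config.stages and not (out / "plates").exists():
            raise FileNotFoundError(
                "no simulated inputs found; run the 'simulate' stage first"
            )
        _analyze(config, out, report)
        lio.write_json(out / "report.json", report)
    return report


def _simulate(config: RunConfig, out: Path) -> None:
    if "ph" in config.assays:
        plate_dir = out / "plates"
        plate_dir.mkdir(exist_ok=True)
        for name in config.ph_presets:
            readings, truth = make_plate(PH_PRESETS[name], config.seed)
            lio.write_plate(plate_dir / f"{name}.csv", readings)
            lio.write_json(plate_dir / f"{name}.truth.json", {"sample_ph": truth.sample_ph})
    if "imaging" in config.assays:
        img_dir = out / "images"
        for name in config.imaging_presets:
            cond_dir = img_dir / name
            cond_dir.mkdir(parents=True, exist_ok=True)
            truth_records = []
            for i in range(config.n_fields):
                field, truth = make_image_field(IMAGING_PRESETS[name], config.seed + i)
                if config.write_images:
                    lio.write_field(cond_dir / f"field_{i:02d}.tif", field)
                truth_records.append(
                    {
                        "field": i,
                        "seed": config.seed + i,
                        "n_organelles": len(truth.organelle_active),
                        "n_active": int(truth.organelle_active.sum()),
                    }
                )
            lio.write_json(cond_dir / "truth.json", truth_records)
    if "proteomics" in config.assays:
        prot_dir = out / "proteome"
        prot_dir.mkdir(exist_ok=True)
        matrix, design, truth = make_proteomics(
            PROTEOMICS_PRESETS[config.proteomics_preset], config.seed
        )
        lio.write_matrix(prot_dir / "protein_groups.tsv", matrix, truth.classes)
        design.to_csv(prot_dir / "design.csv", index=False)
        lio.write_json(prot_dir / "truth.json", {"class_folds": truth.class_folds})


def _analyze(config: RunConfig, out: Path, report: dict) -> None:
    rec = report["recovered"]
    if "ph" in config.assays:
        rows = []
        for name in config.ph_presets:
            res = ph_recovery(name, config.seed)
            rows.append(res)
            rec[f"ph_{name}"] = {
                "value": res["mean_ph"],
                "truth": res["true_ph"],
                "ok": abs(res["mean_ph"] - res["true_ph"]) <= 0.05,
            }
        lio.write_table(out / "ph_summary.csv", pd.DataFrame(rows))
    if "imaging" in config.assays:
        res = active_fraction_recovery(config.seed, config.n_fields, params=config.segmentation)
        rows = []
        for name, r in res["conditions"].items():
            rows.append({"condition": name, **r})
            truth_pct = 100.0 * IMAGING_PRESETS[name].probe_active_fraction
            ok = (
                r["active_percent"] <= 20.0
                if name == "control"
                else abs(r["active_percent"] - truth_pct) <= 5.0
            )
            rec[f"active_percent_{name}"] = {
                "value": r["active_percent"],
                "truth": truth_pct,
                "ok": ok,
            }
        lio.write_table(out / "active_fraction.csv", pd.DataFrame(rows))
    if "proteomics" in config.assays:
        res = enrichment_recovery(config.seed, config.proteomics_preset)
        rows = []
        for cls, fold in sorted(res["class_fold"].items()):
            truth_fold = res["planted_fold"].get(cls)
            row = {"class": cls, "fold": fold, "planted": truth_fold}
            rows.append(row)
            if cls != "other":
                rec[f"fold_{cls}"] = {
                    "value": fold,
                    "truth": truth_fold,
                    "ok": abs(fold - truth_fold) / truth_fold <= 0.15,
                }
        lio.write_table(out / "class_enrichment.csv", pd.DataFrame(rows))


def reproduce(out_dir: str | Path, seed: int = 1, n_fields: int = 20) -> dict:
    """Full desk-scale reproduction run with default presets."""
    return run_pipeline(RunConfig(out_dir=out_dir, seed=seed, n_fields=n_fields))
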