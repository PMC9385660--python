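"""File-format adapters shared by all stages.

Images travel as multi-page 16-bit TIFF (one page per channel, channel names
in the page descriptions), plates as CSV (well, role, ph, I440, I540, group),
protein groups as TSV in the MaxQuant-style convention: 0 marks a missing
LFQ intensity, a blank cell a missing SILAC ratio.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import MultiChannelField
from .phcal import PlateReading

PLATE_COLUMNS = ["well", "role", "ph", "I440", "I540", "group"]


def write_field(path, field: MultiChannelField) -> None:
    """Write a field as multi-page uint16 TIFF, one channel per page."""
    path = Path(path)
    pages = []
    for name, raster in field.channels.items():
        pages.append(np.clip(np.round(raster), 0, 65535).astype(np.uint16))
    with tifffile.TiffWriter(path) as tif:
        for name, page in zip(field.channels, pages):
            tif.write(page, description=name, metadata=None)


def read_field(
    path, pixel_size_um: float = 0.2, field_id: str = "", condition: str = ""
) -> MultiChannelField:
    path = Path(path)
    channels: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            name = (page.description or "").strip() or f"channel{i}"
            channels[name] = page.asarray().astype(float)
    if not channels:
        raise ValueError(f"{path}: no image pages found")
    return MultiChannelField(
        channels=channels,
        pixel_size_um=pixel_size_um,
        field_id=field_id or path.stem,
        condition=condition,
    )


def write_plate(path, readings: list[PlateReading]) -> None:
    rows = [
        {
            "well": r.well,
            "role": r.role,
            "ph": "" if r.buffer_ph is None else r.buffer_ph,
            "I440": r.i440,
            "I540": r.i540,
            "group": r.group,
        }
        for r in readings
    ]
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_plate(path) -> list[PlateReading]:
    df = pd.read_csv(path, dtype={"well": str, "role": str, "group": str})
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: plate CSV missing column(s) {missing}")
    readings = []
    for i, row in df.iterrows():
        try:
            ph = row["ph"]
            readings.append(
                PlateReading(
                    well=row["well"],
                    role=row["role"],
                    buffer_ph=None if pd.isna(ph) else float(ph),
                    i440=float(row["I440"]),
                    i540=float(row["I540"]),
                    group="" if pd.isna(row["group"]) else str(row["group"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return readings


def write_matrix(path, matrix: pd.DataFrame, classes: pd.Series, mode: str = "lfq") -> None:
    """Write a protein-group TSV; missing = 0 (LFQ) or blank (SILAC)."""
    out = matrix.copy()
    if mode == "lfq":
        out = out.fillna(0.0)
    table = pd.concat([classes.rename("class"), out], axis=1)
    table.to_csv(path, sep="\t", index_label="protein")


def read_matrix(path, mode: str = "lfq") -> tuple[pd.DataFrame, pd.Series]:
    """Read a protein-group TSV; returns (matrix with NaN missing, classes)."""
    df = pd.read_csv(path, sep="\t", index_col="protein")
    if "class" not in df.columns:
        raise ValueError(f"{path}: missing 'class' annotation column")
    classes = df.pop("class")
    matrix = df.astype(float)
    if mode == "lfq":
        matrix = matrix.mask(matrix == 0.0)
    return matrix, classes


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.uint16), metadata=None)


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
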