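"""File formats: focus tables (CSV), images (16-bit TIFF + JSON sidecar),
nucleus geometry (JSON).

Schema conventions: coordinates in nm with the origin at the image top-left
pixel center, x rightward, y downward; channels are always named DMC1/RPA in
data files regardless of fluorophore; (nucleus_id, channel, focus_id) is the
unique row key.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from spreadfoci.detect import FocusRecord, Image
from spreadfoci.simulate import GroundTruthFocus, NucleusGeometry

__all__ = [
    "FOCUS_COLUMNS", "CHANNELS", "read_focus_table", "write_focus_table",
    "records_to_table", "table_to_records", "read_image", "write_image",
    "read_geometry", "write_geometry",
]

FOCUS_COLUMNS = (
    "nucleus_id", "channel", "focus_id", "x_nm", "y_nm",
    "major_length_nm", "area_px", "partner_id",
)
_REQUIRED = FOCUS_COLUMNS[:6]
CHANNELS = ("DMC1", "RPA")


class SchemaError(ValueError):
    """A table violates the focus-table schema."""


def _validate_focus_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    for c in ("area_px", "partner_id"):
        if c not in df.columns:
            df[c] = pd.NA
    df = df[list(FOCUS_COLUMNS)].copy()
    for c in ("nucleus_id", "channel", "focus_id"):
        df[c] = df[c].astype(str)
    for c in ("x_nm", "y_nm", "major_length_nm"):
        df[c] = pd.to_numeric(df[c], errors="raise")
    df["area_px"] = pd.to_numeric(df["area_px"], errors="coerce").astype("Int64")

    bad = ~df["channel"].isin(CHANNELS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"row {row + 2}: channel {df['channel'].iloc[row]!r} not in {CHANNELS}"
        )
    nonpos = df["major_length_nm"] <= 0
    if len(df) and nonpos.any():
        row = int(np.flatnonzero(nonpos)[0])
        raise SchemaError(f"row {row + 2}: non-positive major_length_nm")
    dup = df.duplicated(subset=["nucleus_id", "channel", "focus_id"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        key = tuple(df.iloc[row][["nucleus_id", "channel", "focus_id"]])
        raise SchemaError(f"row {row + 2}: duplicate key {key}")
    return df


def read_focus_table(path) -> pd.DataFrame:
    """Read and validate a focus-table CSV (row numbers in errors count the
    header as row 1)."""
    df = pd.read_csv(path, float_precision="round_trip")
    return _validate_focus_table(df)


def records_to_table(
    records: Sequence[Union[FocusRecord, GroundTruthFocus]],
    nucleus_id: str | None = None,
) -> pd.DataFrame:
    """Build a schema-conformant DataFrame from focus records.

    Accepts detection :class:`FocusRecord` rows or simulator ground truth
    (whose ``nucleus_id`` is supplied by the caller or parsed from the
    ``nucleus:channel:index`` focus-id convention).
    """
    rows = []
    for r in records:
        if isinstance(r, FocusRecord):
            rows.append(
                dict(
                    nucleus_id=r.nucleus_id, channel=r.channel, focus_id=r.focus_id,
                    x_nm=r.x_nm, y_nm=r.y_nm, major_length_nm=r.major_length_nm,
                    area_px=r.area_px, partner_id=r.partner_id,
                )
            )
        else:
            nid = nucleus_id or r.focus_id.rsplit(":", 2)[0]
            rows.append(
                dict(
                    nucleus_id=nid, channel=r.channel, focus_id=r.focus_id,
                    x_nm=r.center_xy[0], y_nm=r.center_xy[1],
                    major_length_nm=r.length_nm, area_px=pd.NA,
                    partner_id=r.partner_id,
                )
            )
    df = pd.DataFrame(rows, columns=list(FOCUS_COLUMNS))
    return _validate_focus_table(df) if len(df) else df


def write_focus_table(table, path) -> None:
    """Write a focus table CSV (validates first; full float precision)."""
    if not isinstance(table, pd.DataFrame):
        table = records_to_table(table)
    elif len(table):
        table = _validate_focus_table(table)
    table.to_csv(path, index=False)


def table_to_records(df: pd.DataFrame) -> list[FocusRecord]:
    return [
        FocusRecord(
            nucleus_id=row.nucleus_id, channel=row.channel, focus_id=row.focus_id,
            x_nm=float(row.x_nm), y_nm=float(row.y_nm),
            major_length_nm=float(row.major_length_nm),
            area_px=None if pd.isna(row.area_px) else int(row.area_px),
            partner_id=None if pd.isna(row.partner_id) else str(row.partner_id),
        )
        for row in df.itertuples()
    ]


def write_image(image: Image, path) -> None:
    """16-bit grayscale TIFF plus a ``.json`` sidecar with pixel size and
    provenance fields; pixel size is also embedded in the TIFF description."""
    path = Path(path)
    meta = {
        "pixel_size_nm": image.pixel_size_nm,
        "channel": image.channel,
        "nucleus_id": image.nucleus_id,
        "origin_xy_nm": list(image.origin_xy),
    }
    tifffile.imwrite(path, np.asarray(image.data), description=json.dumps(meta))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_image(path, pixel_size_nm: float | None = None) -> Image:
    """Read a channel TIFF; pixel size comes from the JSON sidecar, the TIFF
    description, or the explicit argument (in that order of preference)."""
    path = Path(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        with tifffile.TiffFile(path) as tf:
            desc = tf.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except json.JSONDecodeError:
                meta = {}
    px = meta.get("pixel_size_nm", pixel_size_nm)
    if px is None:
        raise ValueError(
            f"{path}: no pixel size in sidecar or TIFF metadata; pass pixel_size_nm"
        )
    return Image(
        data=tifffile.imread(path),
        pixel_size_nm=float(px),
        channel=meta.get("channel", ""),
        nucleus_id=meta.get("nucleus_id", ""),
        origin_xy=tuple(meta.get("origin_xy_nm", (0.0, 0.0))),
    )


def write_geometry(geometries: Sequence[NucleusGeometry], path) -> None:
    payload = [
        {
            "nucleus_id": g.nucleus_id,
            "center_xy": list(g.center_xy),
            "semi_axes": list(g.semi_axes),
            "orientation": g.orientation,
        }
        for g in geometries
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_geometry(path) -> dict[str, NucleusGeometry]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for g in payload:
        geo = NucleusGeometry(
            nucleus_id=g["nucleus_id"],
            center_xy=tuple(g["center_xy"]),
            semi_axes=tuple(g["semi_axes"]),
            orientation=float(g.get("orientation", 0.0)),
        )
        out[geo.nucleus_id] = geo
    return out
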