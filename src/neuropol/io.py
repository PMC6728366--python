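"""Readers and writers for the pipeline's table, image and result formats.

Tables are delimited text (tab by default, comma auto-detected); label and
intensity images are single-plane TIFF; results serialise to JSON with a
schema version and an echo of the configuration that produced them.

Annotation coordinates usually originate from image viewers, whose y axis
points down.  All internal math uses a y-up frame with anticlockwise
angles positive, so ``read_cells`` negates y (and supplied angles keep
their on-screen anticlockwise meaning) when ``frame="image_y_down"``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .circstats import wrap_axial, wrap_directional
from .orient import CellRecord, DivisionEvent
from .profilepol import AngularProfile

__all__ = [
    "read_cells",
    "write_cells",
    "read_divisions",
    "read_profile",
    "write_profile",
    "read_label_image",
    "write_label_image",
    "write_result",
    "read_result",
]

SCHEMA_VERSION = 1

REQUIRED_CELL_COLUMNS = ("cell_id", "x", "y", "axial_angle_deg")


class ParseError(ValueError):
    """A table failed to parse; message names the offending line/column."""


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "," if ("," in first and "\t" not in first) else "\t"
    return pd.read_csv(path, sep=sep, comment="#")


def read_cells(path, frame: str = "image_y_down") -> list[CellRecord]:
    """Read a CellRecord table.

    Required columns: cell_id, x, y, axial_angle_deg; optional:
    dir_angle_deg, cell_class.  With ``frame="image_y_down"`` (the
    default; annotations come from image viewers) y is negated on
    ingestion; ``frame="math_y_up"`` takes coordinates as-is.  Angles are
    wrapped on ingestion.  Malformed rows raise ParseError naming the line.
    """
    if frame not in ("image_y_down", "math_y_up"):
        raise ValueError(f"unknown frame {frame!r}")
    df = _read_table(path)
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    y_sign = -1.0 if frame == "image_y_down" else 1.0
    cells = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            dir_angle = row["dir_angle_deg"] if "dir_angle_deg" in df.columns else None
            if dir_angle is not None and pd.isna(dir_angle):
                dir_angle = None
            cells.append(CellRecord(
                cell_id=int(row["cell_id"]),
                x=float(row["x"]),
                y=y_sign * float(row["y"]),
                axial_angle=wrap_axial(float(row["axial_angle_deg"])),
                dir_angle=None if dir_angle is None else wrap_directional(float(dir_angle)),
                cell_class=str(row["cell_class"]) if "cell_class" in df.columns else "hair",
            ))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {line_no}: {exc}") from exc
    return cells


def write_cells(cells: Sequence[CellRecord], path, frame: str = "math_y_up") -> None:
    """Write a CellRecord table (tab-separated).  ``frame`` records which
    convention the written y column uses."""
    y_sign = -1.0 if frame == "image_y_down" else 1.0
    df = pd.DataFrame({
        "cell_id": [c.cell_id for c in cells],
        "x": [c.x for c in cells],
        "y": [y_sign * c.y for c in cells],
        "axial_angle_deg": [c.axial_angle for c in cells],
        "dir_angle_deg": [c.dir_angle if c.dir_angle is not None else np.nan for c in cells],
        "cell_class": [c.cell_class for c in cells],
    })
    with open(path, "w") as fh:
        fh.write(f"# neuropol {__version__} cell table; frame={frame}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_divisions(path, frame: str = "image_y_down") -> list[DivisionEvent]:
    """Read a DivisionEvent table: columns t, d1x, d1y[, d1z], d2x, d2y[,
    d2z], cx, cy[, cz].  3-D columns are optional but must be consistent."""
    df = _read_table(path)
    has_z = all(c in df.columns for c in ("d1z", "d2z", "cz"))
    needed = ["t", "d1x", "d1y", "d2x", "d2y", "cx", "cy"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    y_sign = -1.0 if frame == "image_y_down" else 1.0
    events = []
    for i, row in df.iterrows():
        try:
            if has_z:
                d1 = (row["d1x"], y_sign * row["d1y"], row["d1z"])
                d2 = (row["d2x"], y_sign * row["d2y"], row["d2z"])
                c = (row["cx"], y_sign * row["cy"], row["cz"])
            else:
                d1 = (row["d1x"], y_sign * row["d1y"])
                d2 = (row["d2x"], y_sign * row["d2y"])
                c = (row["cx"], y_sign * row["cy"])
            events.append(DivisionEvent(d1, d2, c, timepoint=float(row["t"])))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {i + 2}: {exc}") from exc
    return events


def read_profile(path) -> AngularProfile:
    """Read a two-column (angle_deg, intensity[, sem]) profile table."""
    df = _read_table(path)
    if "angle_deg" not in df.columns or "intensity" not in df.columns:
        raise ParseError(f"{path}: profile table needs columns angle_deg, intensity")
    sem = df["sem"].to_numpy() if "sem" in df.columns else None
    return AngularProfile(angles=df["angle_deg"].to_numpy(),
                          intensity=df["intensity"].to_numpy(), sem=sem)


def write_profile(profile: AngularProfile, path) -> None:
    cols = {"angle_deg": profile.angles, "intensity": profile.intensity}
    if profile.sem is not None:
        cols["sem"] = profile.sem
    with open(path, "w") as fh:
        fh.write(f"# neuropol {__version__} profile; aligned={profile.aligned} "
                 f"normalized={profile.normalized}\n")
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False)


def read_label_image(path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane 2-D image, got shape {img.shape}")
    return img


def write_label_image(img: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(img, dtype=np.uint16))


def _jsonify(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return obj.to_dict()
        return {k: _jsonify(v) for k, v in asdict(obj).items()}
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_result(result, path, config: dict | None = None,
                 timestamp: bool = False) -> None:
    """Serialise any module result to JSON.

    The file carries schema_version, the package version, an echo of the
    run configuration, and the result payload at full float precision, so
    identical config + seed reruns produce identical files (timestamps
    are off by default for that reason).
    """
    payload = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "config": _jsonify(config or {}),
        "result": _jsonify(result),
    }
    if timestamp:
        import datetime

        payload["timestamp"] = datetime.datetime.now().isoformat()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_result(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
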