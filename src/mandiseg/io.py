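"""File I/O for landmarks, planes and volume tables.

Landmarks are accepted either as JSON
``{"landmarks": [{"name": ..., "position_mm": [x, y, z]}, ...]}`` or as a
Slicer markup fiducial file (``.fcsv``, comma-separated with columns
``id,x,y,z,...,label``).  World coordinates are LPS millimetres; Slicer
files are RAS by default and are converted on read (controllable via the
``ras`` flag, auto-detected from the ``# CoordinateSystem`` header when
present).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .geometry import LANDMARK_NAMES, Landmark, LandmarkSet, Plane
from .segmentation import SegmentVolumes

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_plane",
    "write_plane",
    "write_volumes",
    "read_volumes",
]


def read_landmarks(path, name_map: Optional[Mapping[str, str]] = None,
                   ras: Optional[bool] = None) -> LandmarkSet:
    """Read a landmark set from JSON or Slicer .fcsv.

    ``name_map`` maps file labels to the controlled vocabulary (needed
    when the markup labels differ from the canonical names).  ``ras``
    forces the input coordinate convention; when None it defaults to LPS
    for JSON and to the ``# CoordinateSystem`` header (or RAS) for fcsv.
    """
    path = Path(path)
    name_map = dict(name_map or {})
    if path.suffix.lower() == ".fcsv":
        return _read_fcsv(path, name_map, ras)
    payload = json.loads(path.read_text())
    lms = []
    for entry in payload["landmarks"]:
        name = name_map.get(entry["name"], entry["name"])
        pos = np.asarray(entry["position_mm"], float)
        if ras:
            pos = pos * np.array([-1.0, -1.0, 1.0])
        lms.append(Landmark(name, pos))
    return _build_set(lms)


def _build_set(lms) -> LandmarkSet:
    seen = {lm.name for lm in lms}
    missing = [n for n in LANDMARK_NAMES if n not in seen]
    if missing:
        raise ValueError(
            f"landmark file is missing: {', '.join(missing)}"
        )
    return LandmarkSet(lms)


def _read_fcsv(path: Path, name_map: Dict[str, str],
               ras: Optional[bool]) -> LandmarkSet:
    header_ras = True  # Slicer default
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "CoordinateSystem" in line:
                header_ras = "RAS" in line.upper().split("=")[-1]
            continue
        rows.append(line.split(","))
    use_ras = header_ras if ras is None else ras
    lms = []
    for row in rows:
        if len(row) < 12:
            raise ValueError(f"malformed fcsv row: {','.join(row)!r}")
        label = row[11].strip()
        name = name_map.get(label, label)
        pos = np.array([float(row[1]), float(row[2]), float(row[3])])
        if use_ras:
            pos = pos * np.array([-1.0, -1.0, 1.0])
        lms.append(Landmark(name, pos))
    return _build_set(lms)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).write_text(json.dumps(landmarks.to_dict(), indent=2))


def read_plane(path) -> Plane | Dict[str, Plane]:
    """Read a clipping plane (or per-side 'L'/'R' pair) from JSON."""
    payload = json.loads(Path(path).read_text())
    if "normal" in payload:
        return Plane(np.asarray(payload["normal"], float) /
                     np.linalg.norm(payload["normal"]),
                     float(payload["offset"]),
                     payload.get("label", ""))
    return {
        side: Plane(np.asarray(p["normal"], float) / np.linalg.norm(p["normal"]),
                    float(p["offset"]), p.get("label", ""))
        for side, p in payload.items()
    }


def write_plane(plane: Plane, path) -> None:
    Path(path).write_text(json.dumps({
        "normal": [float(x) for x in plane.normal],
        "offset": plane.offset,
        "label": plane.label,
    }, indent=2))


def write_volumes(volumes: SegmentVolumes, csv_path=None, json_path=None) -> None:
    if csv_path is not None:
        volumes.to_frame().to_csv(csv_path, index=False, float_format="%.6f")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(volumes.to_dict(), indent=2))


def read_volumes(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)
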