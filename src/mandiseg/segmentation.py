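"""Plane-based partition of a mandible mask into anatomical segments.

Pipeline order mirrors the clinical postprocessing workflow: intensity
threshold -> internal-cavity fill (with an optional morphological closing
to seal canal openings) -> clinical-crown clipping -> per-voxel
classification against the five cutting planes -> connected-component
separation of condyle and coronoid process -> volume bookkeeping.

Tie rules (fixed so an independent per-voxel oracle can match exactly):
voxels are classified at their center point; "above the C-point plane"
means strictly positive signed distance; a signed distance of exactly zero
to the median plane assigns the voxel to the left side; zero distance to
the C-point or Mandibular-Angle plane assigns the lower label (ramus,
resp. hemibody).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import LandmarkSet, Plane, SegmentPlanes
from .volume import LABELS, LABEL_NAMES, Volume

__all__ = [
    "SegmentVolumes",
    "threshold_mask",
    "fill_internal_cavities",
    "remove_crowns",
    "classify_point",
    "classify_points",
    "split_coronoid",
    "partition_mandible",
    "compute_volumes",
]

SEGMENTS = ("condyle", "coronoid", "ramus", "hemibody")

_CHUNK = 2_000_000  # foreground voxels per classification chunk


@dataclass(frozen=True)
class SegmentVolumes:
    """Per-side segment volumes in mm^3.

    ``hemimandible`` is the sum of the four segments of its side (so it
    includes the coronoid process); ``total_mandible`` is the sum of the
    two hemimandibles.  Both identities hold exactly at the voxel-count
    level by construction.
    """

    condyle_L: float
    coronoid_L: float
    ramus_L: float
    hemibody_L: float
    condyle_R: float
    coronoid_R: float
    ramus_R: float
    hemibody_R: float

    def segment(self, name: str, side: str) -> float:
        return getattr(self, f"{name}_{side}")

    @property
    def hemimandible_L(self) -> float:
        return self.condyle_L + self.coronoid_L + self.ramus_L + self.hemibody_L

    @property
    def hemimandible_R(self) -> float:
        return self.condyle_R + self.coronoid_R + self.ramus_R + self.hemibody_R

    @property
    def total_mandible(self) -> float:
        return self.hemimandible_L + self.hemimandible_R

    def to_dict(self) -> Dict[str, float]:
        d = asdict(self)
        d["hemimandible_L"] = self.hemimandible_L
        d["hemimandible_R"] = self.hemimandible_R
        d["total_mandible"] = self.total_mandible
        return d

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per side/segment."""
        rows = []
        for side in ("L", "R"):
            for seg in SEGMENTS + ("hemimandible",):
                rows.append(
                    {"side": side, "segment": seg,
                     "volume_mm3": getattr(self, f"{seg}_{side}")
                     if seg != "hemimandible"
                     else getattr(self, f"hemimandible_{side}")}
                )
        rows.append({"side": "both", "segment": "mandible_total",
                     "volume_mm3": self.total_mandible})
        return pd.DataFrame(rows)

    def swapped(self) -> "SegmentVolumes":
        return SegmentVolumes(
            condyle_L=self.condyle_R, coronoid_L=self.coronoid_R,
            ramus_L=self.ramus_R, hemibody_L=self.hemibody_R,
            condyle_R=self.condyle_L, coronoid_R=self.coronoid_L,
            ramus_R=self.ramus_L, hemibody_R=self.hemibody_L,
        )


# ---------------------------------------------------------------------------
# Mask preparation
# ---------------------------------------------------------------------------

def threshold_mask(volume: Volume, lower: float, upper: float = np.inf) -> Volume:
    """Binary mask of voxels with lower <= value <= upper."""
    if lower > upper:
        raise ValueError("lower threshold exceeds upper threshold")
    mask = (volume.values >= lower) & (volume.values <= upper)
    if not mask.any():
        warnings.warn("threshold window selects no voxels", stacklevel=2)
    return volume.with_values(mask)


def _ellipsoid_structure(radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Structuring element of the given physical radius (anisotropy-aware)."""
    r_vox = np.maximum(np.floor(radius_mm / spacing + 1e-9).astype(int), 0)
    if np.all(r_vox == 0):
        return np.ones((1, 1, 1), dtype=bool)
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in r_vox)]
    dist2 = sum(
        (g * s) ** 2 / max(radius_mm, 1e-12) ** 2
        for g, s in zip(grids, spacing)
    )
    return dist2 <= 1.0 + 1e-9


def fill_internal_cavities(mask: Volume, closing_radius_mm: float = 0.0) -> Volume:
    """Convert enclosed background cavities to foreground.

    An optional morphological closing (physical radius, mm) is applied
    first so that narrow openings — the mandibular canal exits at the
    foramina — are sealed before the fill.  Background connectivity is
    6-connected (face neighbours), the standard dual of 26-connected
    foreground.
    """
    values = np.asarray(mask.values, bool)
    if not values.any():
        raise ValueError("mask is empty")
    if closing_radius_mm > 0:
        structure = _ellipsoid_structure(closing_radius_mm, mask.spacing)
        values = ndimage.binary_closing(values, structure=structure)
    background = ~values
    lab, n = ndimage.label(background, structure=ndimage.generate_binary_structure(3, 1))
    if n:
        border = np.zeros_like(values)
        border[0, :, :] = border[-1, :, :] = True
        border[:, 0, :] = border[:, -1, :] = True
        border[:, :, 0] = border[:, :, -1] = True
        outside = np.unique(lab[border & background])
        enclosed = ~np.isin(lab, np.concatenate(([0], outside)))
        values = values | enclosed
    return mask.with_values(values)


def remove_crowns(
    mask: Volume,
    crown_clip: Plane | Mapping[str, Plane],
    median: Plane | None = None,
) -> Volume:
    """Remove foreground voxels beyond the alveolar clipping plane(s).

    ``crown_clip`` is a single plane, or a {'L': Plane, 'R': Plane} pair in
    which case ``median`` decides which plane applies to each voxel.  Clip
    normals must point occlusally (toward the crowns); voxels with strictly
    positive signed distance are removed.
    """
    values = np.asarray(mask.values, bool)
    idx = np.argwhere(values)
    pts = mask.index_to_world(idx)
    if isinstance(crown_clip, Mapping):
        if median is None:
            raise ValueError("per-side crown planes require the median plane")
        side_left = median.signed_distance(pts) >= 0
        remove = np.where(
            side_left,
            crown_clip["L"].signed_distance(pts) > 0,
            crown_clip["R"].signed_distance(pts) > 0,
        )
    else:
        remove = crown_clip.signed_distance(pts) > 0
    n_remove = int(remove.sum())
    if n_remove > 0.5 * len(idx):
        warnings.warn(
            "crown clip removes more than half of the mask "
            "(implausible alveolar plane)", stacklevel=2,
        )
    out = values.copy()
    rm = idx[remove]
    out[rm[:, 0], rm[:, 1], rm[:, 2]] = False
    return mask.with_values(out)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_points(
    points: np.ndarray,
    planes_L: SegmentPlanes,
    planes_R: SegmentPlanes,
) -> np.ndarray:
    """Vectorized provisional labels for an (n, 3) array of points.

    Returns label codes from :data:`mandiseg.volume.LABELS`; condyle codes
    stand for "condyle candidate" (coronoid separation is a connected-
    component refinement, not a pointwise rule).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.zeros(len(pts), dtype=np.uint8)
    left = planes_L.median.signed_distance(pts) >= 0
    for side, planes, in_side in (("L", planes_L, left), ("R", planes_R, ~left)):
        if not in_side.any():
            continue
        p = pts[in_side]
        above = planes.c_point.signed_distance(p) > 0
        ramus = ~above & (planes.mandibular_angle.signed_distance(p) > 0)
        body = ~above & ~ramus
        code = np.empty(len(p), dtype=np.uint8)
        code[above] = LABELS[f"condyle_{side}"]
        code[ramus] = LABELS[f"ramus_{side}"]
        code[body] = LABELS[f"hemibody_{side}"]
        labels[in_side] = code
    return labels


def classify_point(point, planes_L: SegmentPlanes, planes_R: SegmentPlanes) -> str:
    """Label one point; condyle labels are pre-coronoid candidates."""
    code = classify_points(np.asarray(point, float)[None, :], planes_L, planes_R)[0]
    name = LABEL_NAMES[int(code)]
    if name.startswith("condyle"):
        name = name.replace("condyle", "condyle_candidate")
    return name


def split_coronoid(
    mask_above_cpoint: Volume, condylion: np.ndarray
) -> Tuple[Volume, Volume]:
    """Separate the condyle from the coronoid process.

    26-connected components of the above-C-point mask are computed; the
    component containing (or nearest to) the Condylion landmark is the
    condyle, every other component is coronoid.
    """
    values = np.asarray(mask_above_cpoint.values, bool)
    if not values.any():
        warnings.warn("no foreground above the C-point plane", stacklevel=2)
        empty = mask_above_cpoint.with_values(np.zeros_like(values))
        return empty, mask_above_cpoint.with_values(np.zeros_like(values))
    structure = np.ones((3, 3, 3), dtype=bool)
    lab, n = ndimage.label(values, structure=structure)
    if n == 1:
        comp = 1
    else:
        idx = np.argwhere(values)
        pts = mask_above_cpoint.index_to_world(idx)
        d = np.linalg.norm(pts - np.asarray(condylion, float)[None, :], axis=1)
        nearest = idx[int(np.argmin(d))]
        comp = int(lab[tuple(nearest)])
        if d.min() > 2.0 * float(np.max(mask_above_cpoint.spacing)):
            warnings.warn(
                "Condylion lies more than two voxels from the nearest "
                "above-C-point component", stacklevel=2,
            )
    condyle = lab == comp
    coronoid = values & ~condyle
    if n == 1:
        warnings.warn(
            "condyle and coronoid are fused into a single component; "
            "assigning everything above the C-point plane to the condyle",
            stacklevel=2,
        )
    return (
        mask_above_cpoint.with_values(condyle),
        mask_above_cpoint.with_values(coronoid),
    )


def partition_mandible(
    mask: Volume,
    planes_L: SegmentPlanes,
    planes_R: SegmentPlanes,
    landmarks: LandmarkSet,
) -> Volume:
    """Assign every foreground voxel exactly one segment label.

    The input mask is expected to be cavity-filled and crown-clipped.
    Voxel centers are classified against the cutting planes; per side, the
    above-C-point candidates are then split into condyle and coronoid by
    connected components keyed to the Condylion landmark.
    """
    values = np.asarray(mask.values, bool)
    idx = np.argwhere(values)
    if len(idx) == 0:
        raise ValueError("mask is empty")
    labels = np.zeros(mask.shape, dtype=np.uint8)
    for start in range(0, len(idx), _CHUNK):
        chunk = idx[start:start + _CHUNK]
        pts = mask.index_to_world(chunk)
        labels[chunk[:, 0], chunk[:, 1], chunk[:, 2]] = classify_points(
            pts, planes_L, planes_R
        )
    for side in ("L", "R"):
        cand = labels == LABELS[f"condyle_{side}"]
        if not cand.any():
            continue
        condyle, coronoid = split_coronoid(
            mask.with_values(cand), landmarks[f"Co_{side}"]
        )
        labels[np.asarray(coronoid.values, bool)] = LABELS[f"coronoid_{side}"]
    assert int((labels > 0).sum()) == len(idx)  # partition property
    return mask.with_values(labels)


def compute_volumes(labels: Volume) -> SegmentVolumes:
    """Per-segment volumes: voxel count times the voxel volume."""
    vv = labels.voxel_volume
    counts = np.bincount(np.asarray(labels.values, np.uint8).ravel(),
                         minlength=9)
    kwargs = {
        f"{seg}_{side}": float(counts[LABELS[f"{seg}_{side}"]]) * vv
        for side in ("L", "R")
        for seg in SEGMENTS
    }
    return SegmentVolumes(**kwargs)
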