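"""3D cephalometric reference frame and mandibular cutting planes.

The mandible is partitioned by five planes built from named skeletal
landmarks.  The reference frame follows the clinical convention of a
horizontal plane obtained by tilting the Sella--Nasion plane six degrees
downward (anteriorly) about the mid-sagittal normal, with the vertical and
sagittal planes orthogonal to it through Sella.  All coordinates are world
millimetres in LPS orientation (+x left, +y posterior, +z superior), the
convention used by the imaging formats this package reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LANDMARK_NAMES",
    "DegenerateGeometryError",
    "Landmark",
    "LandmarkSet",
    "Plane",
    "ReferenceFrame",
    "SegmentPlanes",
    "midsagittal_plane",
    "build_reference_frame",
    "plane_through_two_points_normal_to",
    "plane_through_three_points",
    "plane_through_point_parallel_to",
    "bisecting_plane",
    "build_mandibular_planes",
]

#: Controlled vocabulary: six midline landmarks plus three per side.
LANDMARK_NAMES = (
    "S", "N", "Ba", "Me", "Bpt", "MSp",
    "Co_L", "Co_R", "Go_L", "Go_R", "Cp_L", "Cp_R",
)

_MIDLINE = ("S", "N", "Ba", "Me", "Bpt", "MSp")
_SIDED = ("Co", "Go", "Cp")

#: Tilt of the horizontal plane below the Sella--Nasion plane, degrees.
HORIZONTAL_TILT_DEG = 6.0

_UNIT_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when landmark geometry does not determine a unique plane."""


def _as_point(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValueError(f"expected a finite 3-vector, got {p!r}")
    return p


def _normalize(v: np.ndarray, context: str = "vector") -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise DegenerateGeometryError(f"{context}: zero-length direction")
    return v / n


@dataclass(frozen=True)
class Landmark:
    """A named anatomical point (world mm)."""

    name: str
    position: np.ndarray

    def __post_init__(self):
        if self.name not in LANDMARK_NAMES:
            raise ValueError(f"unknown landmark name {self.name!r}")
        object.__setattr__(self, "position", _as_point(self.position))


@dataclass(frozen=True)
class Plane:
    """Oriented plane {p : normal . p = offset}; signed distances in mm."""

    normal: np.ndarray
    offset: float
    label: str = ""

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if n.shape != (3,) or not np.all(np.isfinite(n)):
            raise ValueError("plane normal must be a finite 3-vector")
        length = float(np.linalg.norm(n))
        if abs(length - 1.0) > _UNIT_TOL:
            raise ValueError("plane normal must have unit length (within 1e-9)")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    @classmethod
    def from_normal_point(cls, normal, point, label: str = "") -> "Plane":
        n = _normalize(np.asarray(normal, dtype=float), "plane normal")
        p = _as_point(point)
        return cls(n, float(n @ p), label)

    def signed_distance(self, points) -> np.ndarray | float:
        pts = np.asarray(points, dtype=float)
        return pts @ self.normal - self.offset

    def flipped(self) -> "Plane":
        return Plane(-self.normal, -self.offset, self.label)

    def oriented_towards(self, point) -> "Plane":
        """Return this plane with normal pointing toward ``point``."""
        d = float(self.signed_distance(_as_point(point)))
        return self.flipped() if d < 0 else self

    def oriented_along(self, direction) -> "Plane":
        """Return this plane with normal . direction >= 0."""
        if float(self.normal @ np.asarray(direction, float)) < 0:
            return self.flipped()
        return self

    def transformed(self, rotation, translation) -> "Plane":
        """Image of the plane under the rigid map p -> R p + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        n = R @ self.normal
        return Plane(n, self.offset + float(n @ t), self.label)

    def with_label(self, label: str) -> "Plane":
        return Plane(self.normal, self.offset, label)


class LandmarkSet(Mapping[str, Landmark]):
    """Complete set of the 12 landmarks; validates the spec invariants."""

    def __init__(self, landmarks: Iterable[Landmark] | Mapping[str, object]):
        if isinstance(landmarks, Mapping):
            items = [
                lm if isinstance(lm, Landmark) else Landmark(name, lm)
                for name, lm in landmarks.items()
            ]
        else:
            items = list(landmarks)
        self._landmarks: Dict[str, Landmark] = {lm.name: lm for lm in items}
        missing = [n for n in LANDMARK_NAMES if n not in self._landmarks]
        if missing:
            raise ValueError(f"missing landmarks: {', '.join(missing)}")
        self._validate()

    def _validate(self):
        pts = np.array([self[n] for n in LANDMARK_NAMES])
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        iu = np.triu_indices(len(LANDMARK_NAMES), 1)
        if np.any(d[iu] < 1e-9):
            i, j = next(zip(*[idx[d[iu] < 1e-9] for idx in iu]))
            raise ValueError(
                f"coincident landmarks: {LANDMARK_NAMES[i]} and {LANDMARK_NAMES[j]}"
            )
        for names in (("S", "N", "Ba"), ("Go_L", "Go_R", "Me")):
            a, b, c = (self[n] for n in names)
            if np.linalg.norm(np.cross(b - a, c - a)) < 1e-9:
                raise ValueError(f"collinear landmarks: {', '.join(names)}")

    # Mapping interface -------------------------------------------------
    def __getitem__(self, name: str) -> np.ndarray:
        return self._landmarks[name].position.copy()

    def landmark(self, name: str) -> Landmark:
        return self._landmarks[name]

    def __iter__(self):
        return iter(LANDMARK_NAMES)

    def __len__(self):
        return len(LANDMARK_NAMES)

    # Geometry helpers --------------------------------------------------
    def transformed(self, rotation, translation) -> "LandmarkSet":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return LandmarkSet(
            [Landmark(n, R @ self[n] + t) for n in LANDMARK_NAMES]
        )

    def reflected(self, plane: Plane) -> "LandmarkSet":
        """Mirror across ``plane``, swapping left/right landmark names."""
        swap = {}
        for n in LANDMARK_NAMES:
            if n.endswith("_L"):
                swap[n] = n[:-2] + "_R"
            elif n.endswith("_R"):
                swap[n] = n[:-2] + "_L"
            else:
                swap[n] = n
        out = []
        for n in LANDMARK_NAMES:
            p = self[n]
            q = p - 2.0 * float(plane.signed_distance(p)) * plane.normal
            out.append(Landmark(swap[n], q))
        return LandmarkSet(out)

    def to_dict(self) -> dict:
        return {
            "landmarks": [
                {"name": n, "position_mm": [float(x) for x in self[n]]}
                for n in LANDMARK_NAMES
            ]
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "LandmarkSet":
        return cls(
            [
                Landmark(e["name"], np.asarray(e["position_mm"], float))
                for e in payload["landmarks"]
            ]
        )


@dataclass(frozen=True)
class ReferenceFrame:
    """Cephalometric frame: origin at Sella, orthonormal anatomical axes."""

    origin: np.ndarray
    axis_anterior: np.ndarray
    axis_superior: np.ndarray
    axis_left: np.ndarray
    horizontal: Plane
    vertical: Plane
    midsagittal: Plane

    def __post_init__(self):
        axes = np.array([self.axis_anterior, self.axis_left, self.axis_superior])
        gram = axes @ axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal within 1e-9")
        if np.linalg.det(axes) < 0:
            raise ValueError("frame axes must be right-handed")


@dataclass(frozen=True)
class SegmentPlanes:
    """The five cutting planes of one hemimandible.

    ``gonion_menton`` and ``median`` are geometrically shared between the
    two sides; ``condylion_gonion``, ``c_point`` and ``mandibular_angle``
    are side-specific.
    """

    side: str
    condylion_gonion: Plane
    c_point: Plane
    gonion_menton: Plane
    median: Plane
    mandibular_angle: Plane

    def __post_init__(self):
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")


# ---------------------------------------------------------------------------
# Plane constructions
# ---------------------------------------------------------------------------

def midsagittal_plane(S, N, Ba) -> Plane:
    """Plane through Sella, Nasion and Basion.

    Orientation: normal along cross(N - S, Ba - S).  ``build_reference_frame``
    re-orients it toward the subject's left using the sided landmarks.
    """
    S, N, Ba = _as_point(S), _as_point(N), _as_point(Ba)
    n = np.cross(N - S, Ba - S)
    if np.linalg.norm(n) < 1e-9 * max(np.linalg.norm(N - S), 1.0):
        raise DegenerateGeometryError("S, N, Ba are collinear")
    return Plane.from_normal_point(n, S, "midsagittal")


def plane_through_three_points(a, b, c, label: str = "") -> Plane:
    """Plane containing three non-collinear points.

    The normal sign is canonicalized (first nonzero component positive) so
    that any permutation of the arguments yields the identical plane.
    """
    a, b, c = _as_point(a), _as_point(b), _as_point(c)
    n = np.cross(b - a, c - a)
    scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a), 1.0)
    if np.linalg.norm(n) < 1e-9 * scale:
        raise DegenerateGeometryError("points are collinear")
    n = _normalize(n)
    for comp in n:
        if abs(comp) > 1e-12:
            if comp < 0:
                n = -n
            break
    # offset from the centroid minimizes the residual spread over the inputs
    return Plane(n, float(n @ ((a + b + c) / 3.0)), label)


def plane_through_two_points_normal_to(p, q, ref: Plane, label: str = "") -> Plane:
    """Plane through p and q, perpendicular to the reference plane ``ref``.

    Normal = normalize(cross(ref.normal, q - p)): orthogonal to the p-q
    chord and to the reference normal.
    """
    p, q = _as_point(p), _as_point(q)
    d = q - p
    if np.linalg.norm(d) < 1e-9:
        raise DegenerateGeometryError("the two points coincide")
    n = np.cross(ref.normal, d)
    if np.linalg.norm(n) < 1e-9 * np.linalg.norm(d):
        raise DegenerateGeometryError("chord is parallel to the reference normal")
    n = _normalize(n)
    return Plane(n, float(n @ ((p + q) / 2.0)), label)


def plane_through_point_parallel_to(p, ref: Plane, label: str = "") -> Plane:
    """Translate ``ref`` so that it contains ``p`` (normal unchanged)."""
    p = _as_point(p)
    return Plane(ref.normal, float(ref.normal @ p), label or ref.label)


def bisecting_plane(p1: Plane, p2: Plane, anchor, *, wedge_point=None,
                    label: str = "") -> Plane:
    """Plane through ``anchor`` making equal dihedral angles with p1 and p2.

    Two bisectors exist for any non-parallel pair.  By default the parent
    normals are oriented to agree (n1 . n2 >= 0) and the bisector normal is
    normalize(n1 + n2).  When ``wedge_point`` is given, the parents are
    instead oriented so the probe lies on the positive side of both, and the
    bisector of *that* dihedral wedge (the locus of equal signed distances,
    normal proportional to n1 - n2) is returned — this is the anatomically
    interior bisector when the probe sits inside the bone wedge.
    """
    anchor = _as_point(anchor)
    for pl in (p1, p2):
        if abs(float(pl.signed_distance(anchor))) > 1e-3:
            raise ValueError(
                "anchor must lie on both parent planes (within 1e-3 mm)"
            )
    n1, n2 = p1.normal, p2.normal
    cross = np.linalg.norm(np.cross(n1, n2))
    if cross < 1e-9:
        # parallel normals; both planes contain the anchor, so they coincide
        return Plane(n1, float(n1 @ anchor), label or p1.label)
    if wedge_point is None:
        if float(n1 @ n2) < 0:
            n2 = -n2
        n = _normalize(n1 + n2)
    else:
        w = _as_point(wedge_point)
        if float(n1 @ w) - float(n1 @ anchor) < 0:
            n1 = -n1
        if float(n2 @ w) - float(n2 @ anchor) < 0:
            n2 = -n2
        n = _normalize(n1 - n2)
    return Plane(n, float(n @ anchor), label)


# ---------------------------------------------------------------------------
# Reference frame
# ---------------------------------------------------------------------------

def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = _normalize(np.asarray(axis, float))
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def build_reference_frame(landmarks: LandmarkSet) -> ReferenceFrame:
    """Construct the cephalometric reference frame from a landmark set.

    The mid-sagittal plane passes through S, N, Ba (normal toward the
    subject's left, resolved from the Gonion pair).  The horizontal plane is
    the S-N plane perpendicular to the mid-sagittal plane, tilted six
    degrees so that the Nasion end moves inferiorly.  Vertical and sagittal
    planes complete the orthogonal triple through Sella.
    """
    S, N, Ba = landmarks["S"], landmarks["N"], landmarks["Ba"]
    msag = midsagittal_plane(S, N, Ba)
    # orient toward the subject's left using the inter-Gonion direction
    go_lr = landmarks["Go_L"] - landmarks["Go_R"]
    msag = msag.oriented_along(go_lr)

    # plane through S and N perpendicular to the mid-sagittal plane,
    # normal oriented away from Basion (i.e. superiorly)
    pre_tilt = plane_through_two_points_normal_to(S, N, msag)
    if float(pre_tilt.signed_distance(Ba)) > 0:
        pre_tilt = pre_tilt.flipped()

    # 6 degree tilt about the mid-sagittal normal through S.  The plane is
    # tilted *below* the S-N plane: its anterior (Nasion) end moves
    # inferiorly, so Nasion ends up on the positive (superior) side.
    tilt = np.deg2rad(HORIZONTAL_TILT_DEG)
    candidates = []
    for sign in (1.0, -1.0):
        R = _rotation_about_axis(msag.normal, sign * tilt)
        n = R @ pre_tilt.normal
        candidates.append(Plane.from_normal_point(n, S, "horizontal"))
    horizontal = max(candidates, key=lambda pl: float(pl.signed_distance(N)))
    if float(horizontal.signed_distance(N)) < 0:  # pragma: no cover
        raise DegenerateGeometryError("could not resolve the tilt sign")

    axis_superior = horizontal.normal
    axis_left = msag.normal
    axis_anterior = np.cross(axis_left, axis_superior)
    vertical = Plane.from_normal_point(axis_anterior, S, "vertical")
    sagittal = Plane.from_normal_point(axis_left, S, "sagittal")
    return ReferenceFrame(
        origin=S,
        axis_anterior=axis_anterior,
        axis_superior=axis_superior,
        axis_left=axis_left,
        horizontal=horizontal,
        vertical=vertical,
        midsagittal=sagittal,
    )


# ---------------------------------------------------------------------------
# The five mandibular planes
# ---------------------------------------------------------------------------

def build_mandibular_planes(
    landmarks: LandmarkSet,
    frame: ReferenceFrame,
    side: str,
    *,
    bisector_parents: str = "condylion_gonion+gonion_menton",
) -> SegmentPlanes:
    """Construct the five cutting planes for one side.

    Orientation conventions (fixed so downstream half-space labels are
    deterministic): median normal toward the subject's left; C-point plane
    normal = the frame's superior axis; Gonion--Menton normal superior;
    Condylion--Gonion normal anterior; Mandibular-Angle normal oriented so
    Condylion has positive signed distance.

    ``bisector_parents`` selects the parent pair of the Mandibular Angle
    plane: the default bisects the ramus line (Condylion--Gonion) and the
    mandibular base plane (Gonion--Menton); ``"condylion_gonion+c_point"``
    is the literal alternative reading.
    """
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    Co = landmarks[f"Co_{side}"]
    Go = landmarks[f"Go_{side}"]
    Cp = landmarks[f"Cp_{side}"]
    Me = landmarks["Me"]

    median = plane_through_three_points(
        Me, landmarks["Bpt"], landmarks["MSp"], "median"
    ).oriented_along(frame.axis_left)

    co_go = plane_through_two_points_normal_to(
        Co, Go, frame.midsagittal, f"condylion_gonion_{side}"
    ).oriented_along(frame.axis_anterior)

    c_point = plane_through_point_parallel_to(
        Cp, frame.horizontal, f"c_point_{side}"
    )

    go_me = plane_through_three_points(
        landmarks["Go_L"], landmarks["Go_R"], Me, "gonion_menton"
    ).oriented_along(frame.axis_superior)

    if bisector_parents == "condylion_gonion+gonion_menton":
        parent2 = go_me
    elif bisector_parents == "condylion_gonion+c_point":
        parent2 = plane_through_point_parallel_to(Go, c_point)
    else:
        raise ValueError(f"unknown bisector parent pair {bisector_parents!r}")

    # probe on the interior bisector ray of the gonial angle: mean of the
    # unit directions from Gonion toward Condylion and toward Menton
    probe = Go + _normalize(_normalize(Co - Go) + _normalize(Me - Go))
    angle = bisecting_plane(
        co_go, parent2, Go, wedge_point=probe, label=f"mandibular_angle_{side}"
    ).oriented_towards(Co)

    return SegmentPlanes(
        side=side,
        condylion_gonion=co_go,
        c_point=c_point,
        gonion_menton=go_me,
        median=median,
        mandibular_angle=angle,
    )
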