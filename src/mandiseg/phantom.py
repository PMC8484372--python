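"""Parametric mandible phantom with exact ground truth.

The phantom is a constructive solid in canonical LPS world coordinates
(+x left, +y posterior, +z superior): a U-shaped corpus (full-thickness
chin, two lateral arms), two ramus slabs rising posteriorly at the
gonial angle, a condylar neck and ellipsoid per side, a coronoid wedge
per side, and clinical-crown bumps protruding anteriorly from the
symphysis face.  All landmarks are derived
analytically from the construction, and ground-truth segment volumes are
computed by a brute-force per-voxel classifier that is written
independently of the segmentation module (so that segmentation tests are
not self-referential).

Geometric constants that act as cutting surfaces (sigmoid-notch height,
crown clip offset) are placed strictly between voxel centers of the
default grids, so the half-space tie rules never sit on a voxel center.

A per-side condylar/ramal scale factor in (0, 1] emulates the unilateral
or bilateral growth deficit seen in juvenile idiopathic arthritis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .geometry import Landmark, LandmarkSet, Plane
from .segmentation import SegmentVolumes
from .volume import LABELS, Volume

__all__ = [
    "PhantomSpec",
    "PhantomOutput",
    "generate_phantom",
    "mirror_phantom",
    "perturb_landmarks",
    "random_spec",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the mandible phantom (all lengths in mm).

    ``ramus_height`` is the height of the sigmoid notch (the C-point
    level) above the inferior border.  ``s_condyle_*`` scales the condylar
    ellipsoid radii isotropically about its inferior pole; ``s_ramus_*``
    scales the ramus slab cross-section (width and thickness), keeping the
    notch height fixed so the C-point stays at the same level.
    """

    body_width: float = 84.3
    body_length: float = 54.0
    body_height: float = 20.0
    ramus_height: float = 34.05
    ramus_width: float = 16.0
    ramus_thickness: float = 7.2
    gonial_angle_deg: float = 120.0
    condyle_radii: Tuple[float, float, float] = (5.0, 6.5, 6.0)
    coronoid_height: float = 10.0
    coronoid_width: float = 10.0
    s_condyle_L: float = 1.0
    s_condyle_R: float = 1.0
    s_ramus_L: float = 1.0
    s_ramus_R: float = 1.0
    n_teeth: int = 6
    tooth_height: float = 6.0
    tooth_radius: float = 2.0
    spacing: Tuple[float, float, float] | float = 0.4
    intensity_fg: float = 1000.0
    intensity_bg: float = 0.0
    noise_sigma: float = 50.0
    seed: int = 0

    def __post_init__(self):
        lengths = (
            self.body_width, self.body_length, self.body_height,
            self.ramus_height, self.ramus_width, self.ramus_thickness,
            self.coronoid_height, self.coronoid_width,
            self.tooth_height, self.tooth_radius, *self.condyle_radii,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all phantom lengths must be positive")
        for s in (self.s_condyle_L, self.s_condyle_R,
                  self.s_ramus_L, self.s_ramus_R):
            if not 0 < s <= 1:
                raise ValueError("scale factors must lie in (0, 1]")
        if not 90 < self.gonial_angle_deg < 180:
            raise ValueError("gonial angle must lie in (90, 180) degrees")

    @property
    def spacing_vec(self) -> np.ndarray:
        s = self.spacing
        if np.isscalar(s):
            return np.full(3, float(s))
        return np.asarray(s, dtype=float).reshape(3)


@dataclass
class PhantomOutput:
    """Phantom image, mask, landmarks and exact ground truth.

    ``mask`` still contains the crown bumps (the pipeline removes them via
    ``crown_clip``); ``truth`` and ``truth_labels`` describe the
    crown-clipped solid.  ``crown_voxel_count`` is the exact number of
    foreground voxels beyond the clip plane.
    """

    image: Volume
    mask: Volume
    landmarks: LandmarkSet
    truth: SegmentVolumes
    truth_labels: Volume
    crown_clip: Plane
    crown_voxel_count: int
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Derived construction geometry
# ---------------------------------------------------------------------------

class _Construction:
    """Scalar geometry shared by the rasterizer, landmarks and truth."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.y_front = -40.0
        self.y_back = self.y_front + spec.body_length
        self.y_go = self.y_back + 2.0
        # U-shaped corpus: full-thickness chin anteriorly, two lateral
        # arms posteriorly (the lingual space in between is empty)
        self.chin_depth = 14.0
        self.arm_thickness = 16.0
        self.z_cp = spec.ramus_height
        theta = math.radians(spec.gonial_angle_deg - 90.0)
        self.sin_t, self.cos_t = math.sin(theta), math.cos(theta)
        # the flat ramus top stays 2 mm below the sigmoid-notch level, so
        # the notch has clearance: a small landmark jitter of the C-point
        # does not sweep the whole ramus surface across the cutting plane
        self.notch_clearance = 2.0
        self.ramus_len = (self.z_cp - self.notch_clearance) / self.cos_t
        self.x_ramus = spec.body_width / 2.0 - spec.ramus_thickness / 2.0 - 1.5
        if self.x_ramus <= 0:
            raise ValueError("body too narrow for the ramus thickness")
        self.y_ramus_top = self.y_go + self.ramus_len * self.sin_t
        # condyle: ellipsoid anchored 0.3 mm above the notch plane
        self.y_condyle = self.y_ramus_top - 2.75
        self.neck_radius = 2.0
        self.neck_z = (self.z_cp - 4.2, self.z_cp + 0.8)
        # coronoid wedge: triangle in (y, z), apex near the anterior edge
        self.cor_apex_y = self.y_ramus_top - spec.ramus_width + 1.0
        self.cor_z0 = self.z_cp - self.notch_clearance - 1.2
        self.cor_z1 = self.z_cp + spec.coronoid_height
        self.tooth_z = 0.7 * spec.body_height
        self.clip_y = self.y_front - 0.35

    def condyle_geometry(self, side: str):
        """(center, radii) of the condylar ellipsoid for one side."""
        s = getattr(self.spec, f"s_condyle_{side}")
        radii = s * np.asarray(self.spec.condyle_radii)
        sx = 1.0 if side == "L" else -1.0
        center = np.array(
            [sx * self.x_ramus, self.y_condyle, self.z_cp + 0.3 + radii[2]]
        )
        return center, radii

    def landmarks(self) -> LandmarkSet:
        sp = self.spec
        lms = [
            Landmark("S", np.array([0.0, self.y_go + 14.0, 80.0])),
            Landmark("N", np.array([
                0.0,
                self.y_go + 14.0 - 60.0 * math.cos(math.radians(6.0)),
                80.0 + 60.0 * math.sin(math.radians(6.0)),
            ])),
            Landmark("Ba", np.array([0.0, self.y_go + 29.0, 55.0])),
            Landmark("Me", np.array([0.0, self.y_front, 0.0])),
            Landmark("Bpt", np.array([0.0, self.y_front, 0.6 * sp.body_height])),
            # genial tubercles sit on the lingual surface, well posterior of
            # the chin: the depth lever keeps the median plane's yaw
            # well-conditioned under landmark jitter
            Landmark("MSp", np.array([0.0, self.y_front + 12.0,
                                      0.4 * sp.body_height])),
        ]
        for side, sx in (("L", 1.0), ("R", -1.0)):
            center, radii = self.condyle_geometry(side)
            # Condylion: ellipsoid support point in the superior-posterior
            # direction (most superior posterior point of the condylar head)
            d = np.array([0.0, 0.3, 1.0])
            d /= np.linalg.norm(d)
            r2d = radii ** 2 * d
            co = center + r2d / math.sqrt(float(d @ r2d))
            lms.append(Landmark(f"Co_{side}", co))
            lms.append(Landmark(f"Go_{side}",
                                np.array([sx * self.x_ramus, self.y_go, 0.0])))
            # lowest point of the sigmoid notch: on the anterior surface of
            # the condylar neck at notch height
            cp_y = self.y_condyle - self.neck_radius
            lms.append(Landmark(f"Cp_{side}",
                                np.array([sx * self.x_ramus, cp_y, self.z_cp])))
        return LandmarkSet(lms)


def _make_grid(con: _Construction) -> Volume:
    sp = con.spec
    h = sp.spacing_vec
    half_x = sp.body_width / 2.0 + 2.0
    nx = 2 * int(math.ceil(half_x / h[0]))
    y_lo = math.floor(con.y_front - sp.tooth_height - 2.0)
    z_top = max(
        con.condyle_geometry("L")[0][2] + sp.s_condyle_L * sp.condyle_radii[2],
        con.condyle_geometry("R")[0][2] + sp.s_condyle_R * sp.condyle_radii[2],
        con.cor_z1,
    )
    y_hi = con.y_condyle + max(sp.condyle_radii) + 4.0
    ny = int(math.ceil((y_hi - y_lo) / h[1]))
    z_lo = -2.0
    nz = int(math.ceil((z_top + 3.0 - z_lo) / h[2]))
    origin = np.array([
        (0.5 - nx / 2.0) * h[0],
        y_lo + 0.5 * h[1],
        z_lo + 0.5 * h[2],
    ])
    return Volume(np.zeros((nx, ny, nz), dtype=bool), h, origin)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _bbox_slices(grid: Volume, lo, hi):
    """Index slices covering the world-space bounding box [lo, hi]."""
    x, y, z = grid.axis_coordinates()
    coords = (x, y, z)
    out = []
    for a in range(3):
        i0 = int(np.searchsorted(coords[a], lo[a] - 1e-9))
        i1 = int(np.searchsorted(coords[a], hi[a] + 1e-9))
        out.append(slice(max(i0, 0), min(i1, grid.shape[a])))
    return tuple(out)


def _subgrid(grid: Volume, sl):
    x, y, z = grid.axis_coordinates()
    return (
        x[sl[0]][:, None, None],
        y[sl[1]][None, :, None],
        z[sl[2]][None, None, :],
    )


def _paint(target: np.ndarray, grid: Volume, lo, hi, membership) -> None:
    sl = _bbox_slices(grid, lo, hi)
    if any(s.start >= s.stop for s in sl):
        raise ValueError("phantom solid exceeds the voxel grid")
    X, Y, Z = _subgrid(grid, sl)
    target[sl] |= membership(X, Y, Z)


def _rasterize(con: _Construction, grid: Volume):
    """Paint the constructive solid; returns (mask, condyle_mask,
    coronoid_mask, tooth_only_mask)."""
    sp = con.spec
    mask = np.zeros(grid.shape, dtype=bool)
    cond = np.zeros(grid.shape, dtype=bool)
    coro = np.zeros(grid.shape, dtype=bool)

    # U-shaped body: outer box minus the lingual cavity behind the chin,
    # leaving two lateral arms that carry the rami
    hw = sp.body_width / 2.0
    arm = con.arm_thickness
    chin = con.chin_depth

    def body(X, Y, Z):
        outer = ((np.abs(X) <= hw) & (Y >= con.y_front)
                 & (Y <= con.y_back) & (Z >= 0.0) & (Z <= sp.body_height))
        lingual = (np.abs(X) <= hw - arm) & (Y >= con.y_front + chin)
        return outer & ~lingual

    _paint(mask, grid,
           (-hw, con.y_front, 0.0), (hw, con.y_back, sp.body_height), body)

    for side, sx in (("L", 1.0), ("R", -1.0)):
        s_r = getattr(sp, f"s_ramus_{side}")
        wr = sp.ramus_width * s_r
        tr = sp.ramus_thickness * s_r
        xc = sx * con.x_ramus

        def ramus(X, Y, Z, xc=xc, wr=wr, tr=tr):
            a = Z / con.cos_t
            b = a * con.sin_t - (Y - con.y_go)
            return (
                (np.abs(X - xc) <= tr / 2.0)
                & (Z >= 0.0) & (a <= con.ramus_len)
                & (b >= 0.0) & (b <= wr)
            )

        lo = (xc - tr, con.y_go - wr - 1, 0.0)
        hi = (xc + tr, con.y_ramus_top + 1, con.z_cp)
        _paint(mask, grid, lo, hi, ramus)

        # condylar neck (vertical cylinder) + ellipsoid head
        center, radii = con.condyle_geometry(side)

        def neck(X, Y, Z, xc=xc):
            r2 = (X - xc) ** 2 + (Y - con.y_condyle) ** 2
            return (r2 <= con.neck_radius ** 2) \
                & (Z >= con.neck_z[0]) & (Z <= con.neck_z[1])

        nlo = (xc - con.neck_radius, con.y_condyle - con.neck_radius,
               con.neck_z[0])
        nhi = (xc + con.neck_radius, con.y_condyle + con.neck_radius,
               con.neck_z[1])
        _paint(mask, grid, nlo, nhi, neck)
        _paint(cond, grid, nlo, nhi, neck)

        def ellipsoid(X, Y, Z, c=center, r=radii):
            return ((X - c[0]) ** 2 / r[0] ** 2
                    + (Y - c[1]) ** 2 / r[1] ** 2
                    + (Z - c[2]) ** 2 / r[2] ** 2) <= 1.0

        elo, ehi = center - radii, center + radii
        _paint(mask, grid, elo, ehi, ellipsoid)
        _paint(cond, grid, elo, ehi, ellipsoid)

        # coronoid wedge (triangular prism)
        def wedge(X, Y, Z, xc=xc, tr=tr):
            frac = (con.cor_z1 - Z) / (con.cor_z1 - con.cor_z0)
            half = (sp.coronoid_width / 2.0) * frac
            return (
                (np.abs(X - xc) <= tr / 2.0)
                & (Z >= con.cor_z0) & (Z <= con.cor_z1)
                & (np.abs(Y - con.cor_apex_y) <= half)
            )

        wlo = (xc - tr, con.cor_apex_y - sp.coronoid_width, con.cor_z0)
        whi = (xc + tr, con.cor_apex_y + sp.coronoid_width, con.cor_z1)
        _paint(mask, grid, wlo, whi, wedge)
        _paint(coro, grid, wlo, whi, wedge)

    # clinical crowns: cylinders protruding anteriorly from the symphysis
    tooth = np.zeros(grid.shape, dtype=bool)
    if sp.n_teeth > 0:
        xs = np.linspace(-0.22 * sp.body_width, 0.22 * sp.body_width,
                         sp.n_teeth)
        for xt in xs:
            def bump(X, Y, Z, xt=xt):
                r2 = (X - xt) ** 2 + (Z - con.tooth_z) ** 2
                return (r2 <= sp.tooth_radius ** 2) \
                    & (Y >= con.y_front - sp.tooth_height) & (Y <= con.y_front + 1.0)

            blo = (xt - sp.tooth_radius, con.y_front - sp.tooth_height,
                   con.tooth_z - sp.tooth_radius)
            bhi = (xt + sp.tooth_radius, con.y_front + 1.0,
                   con.tooth_z + sp.tooth_radius)
            _paint(tooth, grid, blo, bhi, bump)
    tooth_only = tooth & ~mask
    mask |= tooth
    return mask, cond, coro, tooth_only


# ---------------------------------------------------------------------------
# Independent ground-truth classifier
# ---------------------------------------------------------------------------

def _angle_plane_coeffs(con: _Construction, side: str):
    """(ny, nz, offset) of the mandibular-angle plane, Condylion positive.

    Deliberately written out in scalar form, independent of the geometry
    module: interior bisector of the dihedral wedge at Gonion between the
    Condylion-Gonion plane and the inferior-border (Gonion-Menton) plane.
    """
    lms = con.landmarks()
    co = lms[f"Co_{side}"]
    go = lms[f"Go_{side}"]
    me = lms["Me"]
    dy, dz = co[1] - go[1], co[2] - go[2]
    norm = math.hypot(dy, dz)
    n1y, n1z = -dz / norm, dy / norm          # normal of the Co-Go plane
    n2y, n2z = 0.0, 1.0                       # inferior border plane (z = 0)
    # interior probe: bisector ray of the gonial angle at Gonion
    u1 = np.array([co[0] - go[0], dy, dz]) / np.linalg.norm(co - go)
    u2 = (me - go) / np.linalg.norm(me - go)
    probe = go + (u1 + u2) / np.linalg.norm(u1 + u2)
    if n1y * (probe[1] - go[1]) + n1z * (probe[2] - go[2]) < 0:
        n1y, n1z = -n1y, -n1z
    if n2y * (probe[1] - go[1]) + n2z * (probe[2] - go[2]) < 0:
        n2y, n2z = -n2y, -n2z
    ny, nz = n1y - n2y, n1z - n2z
    norm = math.hypot(ny, nz)
    ny, nz = ny / norm, nz / norm
    off = ny * go[1] + nz * go[2]
    if ny * co[1] + nz * co[2] - off < 0:
        ny, nz, off = -ny, -nz, -off
    return ny, nz, off


def _truth_labels(con: _Construction, grid: Volume, mask: np.ndarray,
                  cond: np.ndarray, coro: np.ndarray) -> np.ndarray:
    """Brute-force per-voxel ground-truth labels of the clipped solid."""
    x, y, z = grid.axis_coordinates()
    labels = np.zeros(grid.shape, dtype=np.uint8)
    coeffs = {s: _angle_plane_coeffs(con, s) for s in ("L", "R")}
    idx = np.argwhere(mask)
    px, py, pz = x[idx[:, 0]], y[idx[:, 1]], z[idx[:, 2]]
    left = px >= 0.0                       # median plane is x = 0 exactly
    above = pz > con.z_cp
    in_cond = cond[idx[:, 0], idx[:, 1], idx[:, 2]]
    in_coro = coro[idx[:, 0], idx[:, 1], idx[:, 2]]
    out = np.zeros(len(idx), dtype=np.uint8)
    for side, sel in (("L", left), ("R", ~left)):
        ny, nz, off = coeffs[side]
        s_above = sel & above
        s_below = sel & ~above
        if np.any(s_above & ~(in_cond | in_coro)):
            raise AssertionError(
                "phantom construction violated: foreground above the "
                "C-point plane outside condyle/coronoid primitives"
            )
        out[s_above & in_cond] = LABELS[f"condyle_{side}"]
        out[s_above & in_coro & ~in_cond] = LABELS[f"coronoid_{side}"]
        ramus_side = ny * py + nz * pz - off > 0.0
        out[s_below & ramus_side] = LABELS[f"ramus_{side}"]
        out[s_below & ~ramus_side] = LABELS[f"hemibody_{side}"]
    labels[idx[:, 0], idx[:, 1], idx[:, 2]] = out
    return labels


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomOutput:
    """Build the phantom: image, mask, landmarks and exact ground truth."""
    con = _Construction(spec)
    grid = _make_grid(con)
    mask, cond, coro, tooth_only = _rasterize(con, grid)
    landmarks = con.landmarks()

    crown_clip = Plane(np.array([0.0, -1.0, 0.0]), -con.clip_y, "crown_clip")
    x, y, z = grid.axis_coordinates()
    beyond = y < con.clip_y
    crown_voxels = mask & beyond[None, :, None]
    crown_count = int(crown_voxels.sum())
    clipped = mask & ~crown_voxels

    labels = _truth_labels(con, grid, clipped, cond, coro)
    if not all((labels == code).any() for code in range(1, 9)):
        raise AssertionError("phantom construction left a segment empty")
    vv = grid.voxel_volume
    counts = np.bincount(labels.ravel(), minlength=9)
    truth = SegmentVolumes(**{
        f"{seg}_{side}": float(counts[LABELS[f"{seg}_{side}"]]) * vv
        for side in ("L", "R")
        for seg in ("condyle", "coronoid", "ramus", "hemibody")
    })

    rng = np.random.default_rng(spec.seed)
    image = (
        spec.intensity_bg
        + (spec.intensity_fg - spec.intensity_bg) * mask.astype(np.float32)
    )
    if spec.noise_sigma > 0:
        image = image + rng.normal(
            0.0, spec.noise_sigma, size=mask.shape
        ).astype(np.float32)

    return PhantomOutput(
        image=grid.with_values(image),
        mask=grid.with_values(mask),
        landmarks=landmarks,
        truth=truth,
        truth_labels=grid.with_values(labels),
        crown_clip=crown_clip,
        crown_voxel_count=crown_count,
        spec=spec,
    )


_SWAP_CODES = np.array([0, 5, 6, 7, 8, 1, 2, 3, 4], dtype=np.uint8)


def mirror_phantom(out: PhantomOutput) -> PhantomOutput:
    """Reflect the phantom across the mid-sagittal (x = 0) lattice plane."""
    grid = out.mask
    x = grid.axis_coordinates()[0]
    if abs(x[0] + x[-1]) > 1e-6:
        raise ValueError("voxel lattice is not symmetric about x = 0; "
                         "reflection would be off-lattice")
    median = Plane(np.array([1.0, 0.0, 0.0]), 0.0, "median")
    reflect = lambda vol, vals: vol.with_values(np.flip(vals, axis=0).copy())
    M = np.diag([-1.0, 1.0, 1.0])
    clip = Plane(M @ out.crown_clip.normal, out.crown_clip.offset,
                 out.crown_clip.label)
    spec = replace(
        out.spec,
        s_condyle_L=out.spec.s_condyle_R, s_condyle_R=out.spec.s_condyle_L,
        s_ramus_L=out.spec.s_ramus_R, s_ramus_R=out.spec.s_ramus_L,
    )
    return PhantomOutput(
        image=reflect(out.image, out.image.values),
        mask=reflect(out.mask, out.mask.values),
        landmarks=out.landmarks.reflected(median),
        truth=out.truth.swapped(),
        truth_labels=reflect(out.truth_labels,
                             _SWAP_CODES[out.truth_labels.values]),
        crown_clip=clip,
        crown_voxel_count=out.crown_voxel_count,
        spec=spec,
    )


def perturb_landmarks(
    landmarks: LandmarkSet, sigma_mm: float, seed=None
) -> LandmarkSet:
    """Isotropic Gaussian jitter of every landmark (re-digitization model)."""
    if sigma_mm < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma_mm == 0:
        return landmarks
    rng = np.random.default_rng(seed)
    return LandmarkSet([
        Landmark(n, landmarks[n] + rng.normal(0.0, sigma_mm, size=3))
        for n in landmarks
    ])


def random_spec(rng: np.random.Generator, spacing: float = 0.8,
                asymmetric: bool = True) -> PhantomSpec:
    """A randomized but geometrically safe phantom specification.

    Sizes vary within +/-8% of the defaults, the gonial angle within
    115-125 degrees, and (optionally) per-side scale factors within
    [0.65, 1.0], the range of condylar deficit the JIA emulation targets.
    """
    jitter = lambda v: float(v * rng.uniform(0.92, 1.08))
    scale = lambda: float(rng.uniform(0.65, 1.0)) if asymmetric else 1.0
    return PhantomSpec(
        body_width=jitter(84.3),
        body_length=jitter(54.0),
        body_height=jitter(20.0),
        ramus_height=jitter(34.05),
        ramus_width=jitter(16.0),
        ramus_thickness=jitter(7.2),
        gonial_angle_deg=float(rng.uniform(115.0, 125.0)),
        condyle_radii=(jitter(5.0), jitter(6.5), jitter(6.0)),
        coronoid_height=jitter(10.0),
        coronoid_width=jitter(10.0),
        s_condyle_L=scale(), s_condyle_R=scale(),
        s_ramus_L=scale(), s_ramus_R=scale(),
        n_teeth=int(rng.integers(4, 9)),
        spacing=spacing,
        noise_sigma=float(rng.uniform(20.0, 60.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
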