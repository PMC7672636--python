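"""Synthetic outer-retina phantom with analytically known ground truth.

The generator emits a :class:`~rpe3d.model.LabelVolume` emulating the
segmented architecture of the outer retina as seen in serial block-face SEM
reconstructions: a monolayer grid of rhomboid RPE cells (1–2 ellipsoidal
nuclei each), slanted apical microvilli interdigitating with photoreceptor
outer-segment (OS) rods, basal infold pockets (sub-RPE spaces), a
Bruch's-membrane (BrM) slab of noisy thickness, and basally clustered
mitochondria.  Every emitted object carries an analytic (grid-independent)
volume/length/angle in :class:`PhantomTruth`, so rasterised measurements can
be validated against closed-form expectations.

Geometry conventions
--------------------
* Grids are indexed ``(z, y, x)``; physical points and semi-axis triples are
  given in ``(x, y, z)`` order, in µm.
* The apical surface faces −y, BrM lies at +y.
* The rhomboid cell shape is realised as a vertical-displacement shear: the
  apical and basal surfaces are planes tilted by ``shear_angle`` about z
  (``y_apical(x) = y0 + tan(shear)·x``, continuous across the monolayer),
  with vertical lateral walls.  This preserves the per-column y-extent of
  every cell (column height = ``cell_body_height`` exactly) and keeps
  cell–cell interfaces planar, so their areas are known in closed form.
* Microvilli and OS are capsules (cylinders with hemispherical caps) whose
  axes lie in the slice (x–y) plane at ``tilt_angle`` degrees from the +x
  direction, i.e. they rise towards −y while leaning in −x for angles
  > 90°.

Overlap policy: objects are constructed pairwise disjoint except for the
deliberate microvillus–OS contact overlap (≈1.5 voxels deep, so 6-connected
face contact survives rasterisation).  Stamping order implements the
precedence BrM < cell body < infold pocket < nucleus < mitochondrion <
microvilli < OS (later wins); the microvillus volume carved away by its
paired OS is subtracted from the analytic truth by exact 1D quadrature of
the circle–circle lens area along the shared axis direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import integrate

from .model import CompartmentKind, LabelTable, LabelVolume, VoxelSpacing

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CellTruth",
    "PhantomError",
    "generate_phantom",
    "rasterise_rod",
    "capsule_volume_um3",
    "ellipsoid_volume_um3",
]


class PhantomError(ValueError):
    """Degenerate phantom specification or scene overflow."""


# ---------------------------------------------------------------------------
# analytic primitives
# ---------------------------------------------------------------------------

def capsule_volume_um3(length_um: float, radius_um: float) -> float:
    """Volume of a capsule (cylinder + two hemispherical caps), µm³."""
    r = radius_um
    return math.pi * r * r * length_um + 4.0 / 3.0 * math.pi * r ** 3


def ellipsoid_volume_um3(semiaxes_um: Sequence[float]) -> float:
    a, b, c = semiaxes_um
    return 4.0 / 3.0 * math.pi * a * b * c


def _lens_area(r1: float, r2: float, d: float) -> float:
    """Intersection area of two discs of radii r1, r2 at centre distance d."""
    if r1 <= 0.0 or r2 <= 0.0 or d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        rmin = min(r1, r2)
        return math.pi * rmin * rmin
    a1 = math.acos((d * d + r1 * r1 - r2 * r2) / (2.0 * d * r1))
    a2 = math.acos((d * d + r2 * r2 - r1 * r1) / (2.0 * d * r2))
    tri = 0.5 * math.sqrt(
        max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    )
    return r1 * r1 * a1 + r2 * r2 * a2 - tri


def _capsule_profile(s: float, length: float, radius: float) -> float:
    """Cross-section radius of a capsule at axial coordinate s (0..length shaft)."""
    if s < 0.0:
        t = radius * radius - s * s
    elif s > length:
        t = radius * radius - (s - length) ** 2
    else:
        return radius
    return math.sqrt(t) if t > 0.0 else 0.0


def capsule_pair_overlap_volume_um3(
    r_a: float, len_a: float,
    r_b: float, len_b: float,
    axial_offset: float, perp_distance: float,
) -> float:
    """Overlap volume of two parallel-axis capsules.

    Capsule *a* spans axial [0, len_a]; capsule *b* spans
    [axial_offset, axial_offset + len_b]; their axes are ``perp_distance``
    apart.  Computed by quadrature of the lens area of the two cross-section
    discs along the common axis direction — exact up to quadrature tolerance.
    """
    lo = max(-r_a, axial_offset - r_b)
    hi = min(len_a + r_a, axial_offset + len_b + r_b)
    if hi <= lo or perp_distance >= r_a + r_b:
        return 0.0

    def integrand(s: float) -> float:
        return _lens_area(
            _capsule_profile(s, len_a, r_a),
            _capsule_profile(s - axial_offset, len_b, r_b),
            perp_distance,
        )

    pts = sorted({lo, hi, 0.0, len_a, axial_offset, axial_offset + len_b})
    pts = [p for p in pts if lo < p < hi]
    val, _err = integrate.quad(integrand, lo, hi, points=pts, limit=200)
    return val


# ---------------------------------------------------------------------------
# rasterisation helpers (voxel-centre-in-solid rule)
# ---------------------------------------------------------------------------

def _spacing_um(spacing: VoxelSpacing) -> Tuple[float, float, float]:
    """(dz, dy, dx) in µm."""
    return spacing.dz * 1e-3, spacing.dy * 1e-3, spacing.dx * 1e-3


def _bbox_slices(lo_um: Sequence[float], hi_um: Sequence[float],
                 spacing: VoxelSpacing, shape: Tuple[int, int, int],
                 ) -> Tuple[Tuple[slice, slice, slice], bool]:
    """Index slices covering a physical (x,y,z) µm bbox; flags clipping."""
    steps = _spacing_um(spacing)  # (dz, dy, dx)
    phys = [(lo_um[2], hi_um[2]), (lo_um[1], hi_um[1]), (lo_um[0], hi_um[0])]
    idx = []
    clipped = False
    for (lo, hi), step, n in zip(phys, steps, shape):
        i0 = int(math.floor(lo / step))
        i1 = int(math.ceil(hi / step)) + 1
        if i0 < 0 or i1 > n:
            clipped = True
        idx.append(slice(max(i0, 0), min(i1, n)))
    return tuple(idx), clipped


def _axis_centers(sl: slice, step_um: float) -> np.ndarray:
    return (np.arange(sl.start, sl.stop) + 0.5) * step_um


def _capsule_mask(sl: Tuple[slice, slice, slice], spacing: VoxelSpacing,
                  p0: Sequence[float], p1: Sequence[float],
                  radius: float) -> np.ndarray:
    """Boolean mask (over slices ``sl``) of centres within ``radius`` of segment."""
    dz, dy, dx = _spacing_um(spacing)
    zc = _axis_centers(sl[0], dz)[:, None, None]
    yc = _axis_centers(sl[1], dy)[None, :, None]
    xc = _axis_centers(sl[2], dx)[None, None, :]
    ax, ay, az = (p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2])
    px = xc - p0[0]
    py = yc - p0[1]
    pz = zc - p0[2]
    seg2 = ax * ax + ay * ay + az * az
    if seg2 == 0.0:
        d2 = px * px + py * py + pz * pz
        return d2 <= radius * radius
    t = (px * ax + py * ay + pz * az) / seg2
    np.clip(t, 0.0, 1.0, out=t)
    d2 = (px - t * ax) ** 2 + (py - t * ay) ** 2 + (pz - t * az) ** 2
    return d2 <= radius * radius


def _ellipsoid_mask(sl: Tuple[slice, slice, slice], spacing: VoxelSpacing,
                    center: Sequence[float],
                    semiaxes: Sequence[float]) -> np.ndarray:
    dz, dy, dx = _spacing_um(spacing)
    zc = (_axis_centers(sl[0], dz) - center[2])[:, None, None] / semiaxes[2]
    yc = (_axis_centers(sl[1], dy) - center[1])[None, :, None] / semiaxes[1]
    xc = (_axis_centers(sl[2], dx) - center[0])[None, None, :] / semiaxes[0]
    return zc * zc + yc * yc + xc * xc <= 1.0


def rasterise_rod(p0_um: Sequence[float], p1_um: Sequence[float],
                  radius_um: float, spacing: VoxelSpacing,
                  shape: Tuple[int, int, int] | None = None) -> np.ndarray:
    """Rasterise a capsule rod: voxels whose centre lies within ``radius_um``
    of the axis segment ``p0_um → p1_um`` (points in (x, y, z) µm).

    The corresponding analytic volume is ``π r² L + (4/3) π r³``
    (:func:`capsule_volume_um3`).  A zero-length segment degenerates to a
    sphere.  If ``shape`` (z, y, x) is omitted, a minimal grid anchored at
    the physical origin and covering the capsule is used; the capsule must
    then lie in the positive octant.
    """
    if any(not np.isfinite(v) for v in (*p0_um, *p1_um, radius_um)):
        raise ValueError("rod endpoints and radius must be finite")
    if radius_um <= 0.0:
        raise ValueError("rod radius must be positive")
    dz, dy, dx = _spacing_um(spacing)
    half_diag = 0.5 * math.sqrt(dx * dx + dy * dy + dz * dz)
    if radius_um < half_diag:
        warnings.warn(
            f"rod radius {radius_um:.3g} µm is below the voxel half-diagonal "
            f"{half_diag:.3g} µm; rasterisation is unreliable",
            stacklevel=2,
        )
    lo = [min(a, b) - radius_um for a, b in zip(p0_um, p1_um)]
    hi = [max(a, b) + radius_um for a, b in zip(p0_um, p1_um)]
    if shape is None:
        if min(lo) < 0.0:
            raise ValueError("without an explicit shape the capsule must lie "
                             "in the positive octant")
        shape = (
            int(math.ceil(hi[2] / dz)) + 1,
            int(math.ceil(hi[1] / dy)) + 1,
            int(math.ceil(hi[0] / dx)) + 1,
        )
    sl, _ = _bbox_slices(lo, hi, spacing, shape)
    out = np.zeros(shape, dtype=bool)
    out[sl] = _capsule_mask(sl, spacing, p0_um, p1_um, radius_um)
    return out


# ---------------------------------------------------------------------------
# spec & truth
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of the synthetic outer-retina scene.

    Lengths in µm unless noted; BrM thickness in nm.  Semi-axis triples are
    (x, y, z).  Defaults reproduce the magnitudes of the reconstructed
    tissue (cell height 6.7 µm, microvilli 5.5 µm at 143°, BrM
    524.4 ± 200.5 nm, nucleus ≈ 141 µm³, mitochondria ≈ 2.8 × 10⁸ nm³ with
    422 per cell, 90 photoreceptor OS per cell) at a desk-scale footprint.
    """

    n_cells_x: int = 2
    n_cells_z: int = 2
    cell_width: float = 18.0
    cell_body_height: float = 6.7
    shear_angle: float = 10.0          # apical/basal plane tilt, degrees
    nuclei_per_cell: int | Sequence[int] = 1
    nucleus_semiaxes: Tuple[float, float, float] = (4.2, 2.5, 3.2)
    microvilli_length: float = 5.5
    tilt_angle: float = 143.0          # degrees from +x, in the slice plane
    rod_radius: float = 0.15
    rods_per_cell: int = 100
    os_per_cell: int = 90
    os_radius: float = 0.35
    os_length: float = 6.0
    brm_mean_thickness: float = 524.4  # nm
    brm_thickness_sd: float = 200.5    # nm
    infold_pockets_per_cell: int = 16
    pocket_radius: float = 0.8
    mito_per_cell: int = 422
    mito_semiaxes: Tuple[float, float, float] = (0.55, 0.35, 0.35)
    mito_basal_fraction: float = 0.8
    spacing: VoxelSpacing = field(default_factory=lambda: VoxelSpacing(50.0, 50.0, 50.0))
    seed: int = 0

    # axial stand-off of the OS tip above the microvillus root, µm
    os_lift: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def nuclei_counts(self) -> List[int]:
        n_cells = self.n_cells_x * self.n_cells_z
        if np.isscalar(self.nuclei_per_cell):
            counts = [int(self.nuclei_per_cell)] * n_cells
        else:
            counts = [int(v) for v in self.nuclei_per_cell]
            if len(counts) != n_cells:
                raise PhantomError(
                    f"nuclei_per_cell sequence length {len(counts)} != "
                    f"number of cells {n_cells}")
        if any(c not in (1, 2) for c in counts):
            raise PhantomError("nuclei_per_cell entries must be 1 or 2")
        return counts

    def validate(self) -> None:
        if self.n_cells_x < 1 or self.n_cells_z < 1:
            raise PhantomError("need at least one cell in each direction")
        positive = {
            "cell_width": self.cell_width,
            "cell_body_height": self.cell_body_height,
            "microvilli_length": self.microvilli_length,
            "rod_radius": self.rod_radius,
            "os_radius": self.os_radius,
            "os_length": self.os_length,
            "brm_mean_thickness": self.brm_mean_thickness,
            "pocket_radius": self.pocket_radius,
        }
        for name, v in positive.items():
            if not np.isfinite(v) or v <= 0:
                raise PhantomError(f"{name} must be positive, got {v!r}")
        if any(a <= 0 for a in self.nucleus_semiaxes) or \
           any(a <= 0 for a in self.mito_semiaxes):
            raise PhantomError("semi-axes must be positive")
        if not 90.0 < self.tilt_angle < 180.0:
            raise PhantomError("tilt_angle must lie in (90, 180) degrees")
        if not 0.0 <= self.shear_angle < 45.0:
            raise PhantomError("shear_angle must lie in [0, 45) degrees")
        if not 0.0 <= self.mito_basal_fraction <= 1.0:
            raise PhantomError("mito_basal_fraction must lie in [0, 1]")
        if self.brm_thickness_sd < 0:
            raise PhantomError("brm_thickness_sd must be >= 0")
        if min(self.rods_per_cell, self.os_per_cell,
               self.mito_per_cell, self.infold_pockets_per_cell) < 0:
            raise PhantomError("object counts must be >= 0")
        if self.os_per_cell > self.rods_per_cell:
            raise PhantomError(
                "os_per_cell must not exceed rods_per_cell (every OS rod is "
                "paired with a microvillus)")
        if self.os_per_cell > 0 and self.os_lift >= self.microvilli_length:
            raise PhantomError("os_lift must be smaller than microvilli_length")
        self.nuclei_counts()


@dataclass
class CellTruth:
    """Analytic per-cell ground truth (volumes before rasterisation)."""

    cell_id: str
    prism_volume_um3: float
    cell_body_volume_um3: float       # prism minus carved organelles/pockets
    nuclei_volumes_um3: List[float]
    microvilli_count: int
    microvilli_length_um: float
    microvilli_total_length_um: float
    microvilli_tilt_deg: float
    microvilli_volume_um3: float      # analytic, OS carve subtracted
    os_count: int
    os_labels: List[int]
    os_volume_um3: float
    pocket_count: int
    pocket_volume_um3: float
    mito_count: int
    mito_volumes_nm3: List[float]
    mito_basal_count: int


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom."""

    cells: Dict[str, CellTruth]
    brm_samples_nm: np.ndarray            # per-column analytic thicknesses
    brm_mean_nm: float
    brm_sd_nm: float
    flat_interface_areas_um2: Dict[Tuple[str, str], float]
    os_contacts: List[Tuple[int, str]]    # (os label, supporting cell id)

    def to_json_dict(self) -> dict:
        return {
            "cells": {
                cid: {
                    "prism_volume_um3": t.prism_volume_um3,
                    "cell_body_volume_um3": t.cell_body_volume_um3,
                    "nuclei_volumes_um3": t.nuclei_volumes_um3,
                    "microvilli_count": t.microvilli_count,
                    "microvilli_length_um": t.microvilli_length_um,
                    "microvilli_total_length_um": t.microvilli_total_length_um,
                    "microvilli_tilt_deg": t.microvilli_tilt_deg,
                    "microvilli_volume_um3": t.microvilli_volume_um3,
                    "os_count": t.os_count,
                    "os_labels": t.os_labels,
                    "os_volume_um3": t.os_volume_um3,
                    "pocket_count": t.pocket_count,
                    "pocket_volume_um3": t.pocket_volume_um3,
                    "mito_count": t.mito_count,
                    "mito_volumes_nm3": t.mito_volumes_nm3,
                    "mito_basal_count": t.mito_basal_count,
                }
                for cid, t in self.cells.items()
            },
            "brm": {
                "mean_nm": self.brm_mean_nm,
                "sd_nm": self.brm_sd_nm,
                "n_columns": int(self.brm_samples_nm.size),
            },
            "flat_interface_areas_um2": {
                f"{a}|{b}": area
                for (a, b), area in self.flat_interface_areas_um2.items()
            },
            "os_contacts": [[lab, cid] for lab, cid in self.os_contacts],
        }


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

_EDGE_MARGIN = 0.4       # background frame around the scene, µm
_FACE_MARGIN = 0.15      # clearance of carved organelles from cell faces, µm
_BRM_GAP = 0.3           # background gap between basal surface and BrM, µm
_ROOT_CLEARANCE_VOX = 1.2  # microvillus root stand-off above apical plane, voxels


class _Scene:
    """Derived scene geometry for a validated spec (lengths in µm)."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        s = spec
        self.theta = math.radians(s.tilt_angle)
        self.ux, self.uy = math.cos(self.theta), -math.sin(self.theta)
        self.slope = math.tan(math.radians(s.shear_angle))
        # perpendicular distance between parallel rod axes per unit Δx of
        # root offset along the (sheared) apical plane
        self.q = abs(math.sin(self.theta) + self.slope * math.cos(self.theta))
        if s.rods_per_cell > 0 and self.q <= 1e-6:
            raise PhantomError("tilt/shear combination leaves rods parallel "
                               "to the apical plane")
        self.reach = (s.os_lift + s.os_length) if s.os_per_cell > 0 else 0.0
        self.reach = max(self.reach, s.microvilli_length if s.rods_per_cell else 0.0)
        r_max = max(s.os_radius, s.rod_radius) if s.rods_per_cell else 0.0

        drift_neg = self.reach * max(0.0, -self.ux) + r_max
        drift_pos = self.reach * max(0.0, self.ux) + r_max
        self.x0 = _EDGE_MARGIN + drift_neg
        self.total_wx = s.n_cells_x * s.cell_width
        self.extent_x = self.x0 + self.total_wx + drift_pos + _EDGE_MARGIN

        self.z0 = _EDGE_MARGIN
        self.total_wz = s.n_cells_z * s.cell_width
        self.extent_z = self.z0 + self.total_wz + _EDGE_MARGIN

        rise = self.reach * (-self.uy) + r_max if s.rods_per_cell else 0.0
        self.ya0 = _EDGE_MARGIN + rise          # apical plane y at x = x0
        self.basal_max = (self.ya0 + self.slope * self.total_wx
                          + s.cell_body_height)
        self.brm_y0 = self.basal_max + _BRM_GAP
        self.brm_tmax = (s.brm_mean_thickness + 5.0 * s.brm_thickness_sd) * 1e-3
        self.extent_y = self.brm_y0 + self.brm_tmax + _EDGE_MARGIN

        dz, dy, dx = _spacing_um(s.spacing)
        self.shape = (
            int(math.ceil(self.extent_z / dz)),
            int(math.ceil(self.extent_y / dy)),
            int(math.ceil(self.extent_x / dx)),
        )

    def y_apical(self, x_um) -> np.ndarray | float:
        return self.ya0 + self.slope * (np.asarray(x_um) - self.x0)

    def cell_origin(self, ix: int, iz: int) -> Tuple[float, float]:
        return (self.x0 + ix * self.spec.cell_width,
                self.z0 + iz * self.spec.cell_width)


def _stamp(grid: np.ndarray, sl, mask: np.ndarray, label: int) -> None:
    grid[sl][mask] = label


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size, floor: float) -> np.ndarray:
    draws = rng.normal(mean, sd, size=size)
    return np.maximum(draws, floor)


def generate_phantom(spec: PhantomSpec) -> Tuple[LabelVolume, PhantomTruth]:
    """Generate the synthetic outer-retina scene described by ``spec``.

    Deterministic for a fixed seed.  Returns the rasterised label volume and
    the analytic ground truth.  Raises :class:`PhantomError` for degenerate
    specs or scenes that do not fit their grid.
    """
    spec.validate()
    scene = _Scene(spec)
    sp = spec.spacing
    dz, dy, dx = _spacing_um(sp)
    grid = np.zeros(scene.shape, dtype=np.uint16)

    nuclei_counts = spec.nuclei_counts()
    n_cells = spec.n_cells_x * spec.n_cells_z
    ss = np.random.SeedSequence(spec.seed)
    # fixed spawning order keeps partial scenes reproducible: one stream for
    # BrM, then per cell one each for pockets, mitochondria, rod jitter
    streams = ss.spawn(1 + 3 * n_cells)
    rng_brm = np.random.default_rng(streams[0])

    table: Dict[int, Tuple[str, CompartmentKind]] = {}
    next_label = 1

    def new_label(cell_id: str, kind: CompartmentKind) -> int:
        nonlocal next_label
        lab = next_label
        table[lab] = (cell_id, kind)
        next_label += 1
        return lab

    # ---- Bruch's membrane -------------------------------------------------
    brm_label = new_label("tissue", CompartmentKind.BRUCHS_MEMBRANE)
    bx0, bx1 = scene.x0, scene.x0 + scene.total_wx
    bz0, bz1 = scene.z0, scene.z0 + scene.total_wz
    sl_brm, clipped = _bbox_slices(
        (bx0, scene.brm_y0, bz0),
        (bx1, scene.brm_y0 + scene.brm_tmax, bz1),
        sp, scene.shape)
    if clipped:
        raise PhantomError("scene overflow: BrM slab exceeds grid")
    xs = _axis_centers(sl_brm[2], dx)
    zs = _axis_centers(sl_brm[0], dz)
    in_x = (xs >= bx0) & (xs < bx1)
    in_z = (zs >= bz0) & (zs < bz1)
    t_field = _truncated_normal(
        rng_brm, spec.brm_mean_thickness * 1e-3, spec.brm_thickness_sd * 1e-3,
        (zs.size, xs.size), floor=dy)
    np.minimum(t_field, scene.brm_tmax, out=t_field)
    yc = _axis_centers(sl_brm[1], dy)[None, :, None]
    brm_mask = (yc >= scene.brm_y0) & (yc < scene.brm_y0 + t_field[:, None, :])
    brm_mask &= in_z[:, None, None] & in_x[None, None, :]
    _stamp(grid, sl_brm, brm_mask, brm_label)
    brm_samples_nm = (t_field[np.ix_(in_z, in_x)] * 1e3).ravel()

    # ---- cells ------------------------------------------------------------
    h = spec.cell_body_height
    cell_ids: List[str] = []
    cell_truths: Dict[str, CellTruth] = {}
    os_contacts: List[Tuple[int, str]] = []

    # analytic carve of one paired microvillus by its OS (identical geometry
    # for every pair)
    d_contact = 0.0
    carve_per_pair = 0.0
    if spec.os_per_cell > 0:
        overlap = 1.5 * dx
        d_contact = spec.rod_radius + spec.os_radius - overlap
        if d_contact <= 0:
            raise PhantomError("rod radii too small for the contact scheme")
        carve_per_pair = capsule_pair_overlap_volume_um3(
            spec.rod_radius, spec.microvilli_length,
            spec.os_radius, spec.os_length,
            axial_offset=spec.os_lift, perp_distance=d_contact)

    cell_index = 0
    for iz in range(spec.n_cells_z):
        for ix in range(spec.n_cells_x):
            cid = f"cell_{ix}_{iz}"
            cell_ids.append(cid)
            cx0, cz0 = scene.cell_origin(ix, iz)
            cx1, cz1 = cx0 + spec.cell_width, cz0 + spec.cell_width

            rng_pock = np.random.default_rng(streams[1 + 3 * cell_index])
            rng_mito = np.random.default_rng(streams[2 + 3 * cell_index])
            rng_rods = np.random.default_rng(streams[3 + 3 * cell_index])

            # cell-body prism (sheared slab between slanted planes)
            body_label = new_label(cid, CompartmentKind.CELL_BODY)
            sl_cell, clipped = _bbox_slices(
                (cx0, scene.y_apical(cx0) - dy, cz0),
                (cx1, scene.y_apical(cx1) + h + dy, cz1),
                sp, scene.shape)
            if clipped:
                raise PhantomError("scene overflow: cell body exceeds grid")
            xs = _axis_centers(sl_cell[2], dx)
            zs = _axis_centers(sl_cell[0], dz)
            ysc = _axis_centers(sl_cell[1], dy)
            ytop = scene.y_apical(xs)[None, None, :]
            body = ((ysc[None, :, None] >= ytop)
                    & (ysc[None, :, None] < ytop + h)
                    & (xs >= cx0)[None, None, :] & (xs < cx1)[None, None, :]
                    & (zs >= cz0)[:, None, None] & (zs < cz1)[:, None, None])
            _stamp(grid, sl_cell, body, body_label)

            # local occupancy (carved objects, grid resolution) for
            # non-overlap rejection tests
            occ = np.zeros_like(body)
            origin = (sl_cell[0].start, sl_cell[1].start, sl_cell[2].start)

            def local(sl_obj):
                out = tuple(
                    slice(s.start - o, s.stop - o)
                    for s, o in zip(sl_obj, origin)
                )
                if any(s.start < 0 or s.stop > n
                       for s, n in zip(out, occ.shape)):
                    return None
                return out

            def carve_object(center, semiaxes, label):
                """Rasterise an interior ellipsoid; returns False on collision."""
                pad = math.sqrt(dx * dx + dy * dy + dz * dz)
                lo = tuple(center[i] - semiaxes[i] - 2 * pad for i in range(3))
                hi = tuple(center[i] + semiaxes[i] + 2 * pad for i in range(3))
                sl_obj, clip = _bbox_slices(lo, hi, sp, scene.shape)
                loc = local(sl_obj)
                if clip or loc is None:
                    return False
                # inflate by one voxel diagonal so accepted objects keep a
                # >= 1 voxel gap (26-connected components stay separate)
                inflated = tuple(a + pad for a in semiaxes)
                test = _ellipsoid_mask(sl_obj, sp, center, inflated)
                if occ[loc][test].any():
                    return False
                exact = _ellipsoid_mask(sl_obj, sp, center, semiaxes)
                occ[loc] |= test  # reserve the inflated envelope
                _stamp(grid, sl_obj, exact, label)
                return True

            # --- nuclei (deterministic placement) ---
            xc_cell = 0.5 * (cx0 + cx1)
            zc_cell = 0.5 * (cz0 + cz1)
            nax, nay, naz = spec.nucleus_semiaxes
            n_nuclei = nuclei_counts[cell_index]
            clearance_y = math.sqrt(nay ** 2 + (scene.slope * nax) ** 2)
            if clearance_y + _FACE_MARGIN > h / 2:
                raise PhantomError("nucleus does not fit the cell height")
            if n_nuclei == 1:
                centers = [(xc_cell, 0.0, zc_cell)]
            else:
                off = nax + _FACE_MARGIN
                if off + nax + _FACE_MARGIN > spec.cell_width / 2:
                    raise PhantomError("two nuclei do not fit the cell width")
                centers = [(xc_cell - off, 0.0, zc_cell),
                           (xc_cell + off, 0.0, zc_cell)]
            nuclei_volumes = []
            for (nx_, _, nz_) in centers:
                ny_ = float(scene.y_apical(nx_)) + h / 2
                lab = new_label(cid, CompartmentKind.NUCLEUS)
                if not carve_object((nx_, ny_, nz_), (nax, nay, naz), lab):
                    raise PhantomError("nucleus placement collision")
                nuclei_volumes.append(ellipsoid_volume_um3((nax, nay, naz)))

            # --- basal infold pockets (random, basal third) ---
            pocket_volume = 0.0
            n_pockets = 0
            if spec.infold_pockets_per_cell > 0:
                r = spec.pocket_radius
                pocket_label = new_label(cid, CompartmentKind.BASAL_INFOLD_SPACE)
                cl = r * math.sqrt(1 + scene.slope ** 2) + _FACE_MARGIN
                lo_rel, hi_rel = 2 * h / 3 + cl, h - cl
                if hi_rel <= lo_rel:
                    raise PhantomError("pocket radius too large for the basal third")
                tries = 0
                max_tries = 400 * spec.infold_pockets_per_cell
                while n_pockets < spec.infold_pockets_per_cell:
                    if tries > max_tries:
                        raise PhantomError("could not place basal infold pockets")
                    tries += 1
                    px = rng_pock.uniform(cx0 + r + _FACE_MARGIN,
                                          cx1 - r - _FACE_MARGIN)
                    pz = rng_pock.uniform(cz0 + r + _FACE_MARGIN,
                                          cz1 - r - _FACE_MARGIN)
                    py = float(scene.y_apical(px)) + rng_pock.uniform(lo_rel, hi_rel)
                    if carve_object((px, py, pz), (r, r, r), pocket_label):
                        n_pockets += 1
                        pocket_volume += 4.0 / 3.0 * math.pi * r ** 3

            # --- mitochondria (random; basally clustered) ---
            mito_volumes_nm3: List[float] = []
            mito_basal = 0
            if spec.mito_per_cell > 0:
                mito_label = new_label(cid, CompartmentKind.MITOCHONDRION)
                placed = 0
                tries = 0
                max_tries = 600 * spec.mito_per_cell
                while placed < spec.mito_per_cell:
                    if tries > max_tries:
                        raise PhantomError("could not place mitochondria "
                                           "without overlap")
                    tries += 1
                    axes = tuple(a * rng_mito.uniform(0.7, 1.3)
                                 for a in spec.mito_semiaxes)
                    basal = rng_mito.random() < spec.mito_basal_fraction
                    cl = (math.sqrt(axes[1] ** 2 + (scene.slope * axes[0]) ** 2)
                          + 0.1)
                    if basal:
                        lo_rel, hi_rel = 2 * h / 3 + cl, h - cl
                    else:
                        lo_rel, hi_rel = cl, 2 * h / 3 - cl
                    if hi_rel <= lo_rel:
                        continue
                    mx = rng_mito.uniform(cx0 + axes[0] + _FACE_MARGIN,
                                          cx1 - axes[0] - _FACE_MARGIN)
                    mz = rng_mito.uniform(cz0 + axes[2] + _FACE_MARGIN,
                                          cz1 - axes[2] - _FACE_MARGIN)
                    my = float(scene.y_apical(mx)) + rng_mito.uniform(lo_rel, hi_rel)
                    if carve_object((mx, my, mz), axes, mito_label):
                        placed += 1
                        mito_volumes_nm3.append(ellipsoid_volume_um3(axes) * 1e9)
                        mito_basal += int(basal)

            # --- microvilli and photoreceptor outer segments ---
            mv_count = 0
            os_labels_cell: List[int] = []
            if spec.rods_per_cell > 0:
                mv_label = new_label(cid, CompartmentKind.MICROVILLI)
                margin_x = max(0.9, (2 * spec.os_radius + 0.1) / (2 * scene.q)
                               if spec.os_per_cell else 0.3)
                px_pitch = (2 * spec.os_radius + 0.15) / scene.q \
                    if spec.os_per_cell else (2 * spec.rod_radius + 0.15) / scene.q
                pz_pitch = max(2 * spec.os_radius + 0.15,
                               d_contact + spec.os_radius + spec.rod_radius + 0.18) \
                    if spec.os_per_cell else 2 * spec.rod_radius + 0.15
                margin_z = 0.45
                nx_sites = int((spec.cell_width - 2 * margin_x) // px_pitch) + 1
                nz_sites = int((spec.cell_width - 2 * margin_z - d_contact)
                               // pz_pitch) + 1
                if nx_sites * nz_sites < spec.rods_per_cell:
                    raise PhantomError(
                        f"cell footprint fits only {nx_sites * nz_sites} rod "
                        f"sites < rods_per_cell={spec.rods_per_cell}")
                jitter = 0.02
                site = 0
                for jz in range(nz_sites):
                    for jx in range(nx_sites):
                        if site >= spec.rods_per_cell:
                            break
                        xr = (cx0 + margin_x + jx * px_pitch
                              + rng_rods.uniform(-jitter, jitter))
                        zr = (cz0 + margin_z + jz * pz_pitch
                              + rng_rods.uniform(-jitter, jitter))
                        yr = (float(scene.y_apical(xr)) - spec.rod_radius
                              - _ROOT_CLEARANCE_VOX * dy)
                        p0 = (xr, yr, zr)
                        p1 = (xr + spec.microvilli_length * scene.ux,
                              yr + spec.microvilli_length * scene.uy, zr)
                        lo = [min(a, b) - spec.rod_radius for a, b in zip(p0, p1)]
                        hi = [max(a, b) + spec.rod_radius for a, b in zip(p0, p1)]
                        sl_rod, clip = _bbox_slices(lo, hi, sp, scene.shape)
                        if clip:
                            raise PhantomError("scene overflow: microvillus "
                                               "exceeds grid")
                        mask = _capsule_mask(sl_rod, sp, p0, p1, spec.rod_radius)
                        _stamp(grid, sl_rod, mask, mv_label)
                        mv_count += 1

                        if site < spec.os_per_cell:
                            q0 = (xr + spec.os_lift * scene.ux,
                                  yr + spec.os_lift * scene.uy,
                                  zr + d_contact)
                            q1 = (q0[0] + spec.os_length * scene.ux,
                                  q0[1] + spec.os_length * scene.uy, q0[2])
                            lo = [min(a, b) - spec.os_radius for a, b in zip(q0, q1)]
                            hi = [max(a, b) + spec.os_radius for a, b in zip(q0, q1)]
                            sl_os, clip = _bbox_slices(lo, hi, sp, scene.shape)
                            if clip:
                                raise PhantomError("scene overflow: outer "
                                                   "segment exceeds grid")
                            os_lab = new_label("photoreceptors",
                                               CompartmentKind.OUTER_SEGMENT)
                            mask = _capsule_mask(sl_os, sp, q0, q1, spec.os_radius)
                            _stamp(grid, sl_os, mask, os_lab)
                            os_labels_cell.append(os_lab)
                            os_contacts.append((os_lab, cid))
                        site += 1

            mv_capsule = capsule_volume_um3(spec.microvilli_length, spec.rod_radius)
            mv_volume = mv_count * mv_capsule - len(os_labels_cell) * carve_per_pair
            os_volume = len(os_labels_cell) * capsule_volume_um3(
                spec.os_length, spec.os_radius)

            prism = spec.cell_width * spec.cell_width * h
            carved = (sum(nuclei_volumes) + pocket_volume
                      + sum(mito_volumes_nm3) * 1e-9)
            cell_truths[cid] = CellTruth(
                cell_id=cid,
                prism_volume_um3=prism,
                cell_body_volume_um3=prism - carved,
                nuclei_volumes_um3=nuclei_volumes,
                microvilli_count=mv_count,
                microvilli_length_um=spec.microvilli_length,
                microvilli_total_length_um=mv_count * spec.microvilli_length,
                microvilli_tilt_deg=spec.tilt_angle,
                microvilli_volume_um3=mv_volume,
                os_count=len(os_labels_cell),
                os_labels=os_labels_cell,
                os_volume_um3=os_volume,
                pocket_count=n_pockets,
                pocket_volume_um3=pocket_volume,
                mito_count=len(mito_volumes_nm3),
                mito_volumes_nm3=mito_volumes_nm3,
                mito_basal_count=mito_basal,
            )
            cell_index += 1

    # ---- analytic flat cell–cell interface areas --------------------------
    # x-neighbours share the plane x = const over the full slab: area = h·w;
    # z-neighbours share the sheared parallelogram cross-section: also h·w
    # (vertical shear preserves in-plane area).
    interface_areas: Dict[Tuple[str, str], float] = {}
    area = h * spec.cell_width
    for iz in range(spec.n_cells_z):
        for ix in range(spec.n_cells_x):
            a = f"cell_{ix}_{iz}"
            if ix + 1 < spec.n_cells_x:
                interface_areas[tuple(sorted((a, f"cell_{ix + 1}_{iz}")))] = area
            if iz + 1 < spec.n_cells_z:
                interface_areas[tuple(sorted((a, f"cell_{ix}_{iz + 1}")))] = area

    vol = LabelVolume(grid=grid, spacing=sp, table=LabelTable(table))
    truth = PhantomTruth(
        cells=cell_truths,
        brm_samples_nm=brm_samples_nm,
        brm_mean_nm=float(brm_samples_nm.mean()) if brm_samples_nm.size else 0.0,
        brm_sd_nm=float(brm_samples_nm.std(ddof=1)) if brm_samples_nm.size > 1 else 0.0,
        flat_interface_areas_um2=interface_areas,
        os_contacts=os_contacts,
    )
    return vol, truth
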