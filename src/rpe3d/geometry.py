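"""Linear and angular measurements on label volumes.

Implements the manual measurement protocol used on the serial stacks —
quantities sampled on every ``slice_interval``-th section, a fixed number of
measurements per sampled section — as seeded, reproducible estimators:

* microvillus length and tilt angle, measured per in-plane microvillus
  segment;
* RPE cell-body height (excluding microvilli), per x-column of the cell
  footprint, plus the combined epithelium height (body + microvilli);
* Bruch's-membrane thickness, per x-column under the cell footprints.

Angle convention: angles are measured in the slice (x–y) plane between the
+x direction (the apical tangent of the monolayer) and the chord from a
segment's root (its apical-surface end, at larger y) to its tip, in
(0°, 180°).  A rod perpendicular to the apical plane therefore measures
90°, and rods leaning towards −x measure > 90°.

Lengths are geodesic distances along the 2D skeleton of each segment.  The
raw 8-connected pixel chain over-estimates the length of oblique straight
segments by up to ~8% (staircase effect), so the chain is resampled into
chords spanning several pixels before summation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .model import CompartmentKind, LabelVolume, compartment_mask

__all__ = [
    "SamplingScheme",
    "LinearMeasurementSet",
    "microvillus_geometry",
    "rpe_height",
    "combined_height",
    "brm_thickness",
]

logger = logging.getLogger(__name__)

# in-plane segments smaller than this are fragments of near-tangent rod
# sections and are not measured (a manual protocol would skip specks too)
_MIN_SEGMENT_PIXELS = 25
# skeleton chain resampling stride, pixels (staircase correction)
_CHORD_STRIDE = 5


@dataclass(frozen=True)
class SamplingScheme:
    """Measure every ``slice_interval``-th slice, ``measurements_per_slice``
    seeded-random measurements per sampled slice."""

    slice_interval: int = 50
    measurements_per_slice: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slice_interval < 1:
            raise ValueError("slice_interval must be >= 1")
        if self.measurements_per_slice < 1:
            raise ValueError("measurements_per_slice must be >= 1")

    def slices(self, n_slices: int) -> range:
        return range(0, n_slices, self.slice_interval)


@dataclass
class LinearMeasurementSet:
    """A named set of scalar samples with mean ± sample SD."""

    quantity: str
    units: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 1:
            raise ValueError(f"{self.quantity}: no samples collected")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=1)) if self.n > 1 else 0.0


# ---------------------------------------------------------------------------
# skeleton helpers
# ---------------------------------------------------------------------------

def _skeleton_graph(seg_mask: np.ndarray, dy_um: float, dx_um: float,
                    ) -> Optional[nx.Graph]:
    """8-connected weighted graph over the skeleton pixels of a 2D mask."""
    skel = skeletonize(seg_mask)
    ys, xs = np.nonzero(skel)
    if ys.size < 2:
        return None
    g = nx.Graph()
    pix = set(zip(ys.tolist(), xs.tolist()))
    for y, x in pix:
        for ddy in (-1, 0, 1):
            for ddx in (-1, 0, 1):
                if ddy == ddx == 0:
                    continue
                nb = (y + ddy, x + ddx)
                if nb in pix:
                    w = math.hypot(ddy * dy_um, ddx * dx_um)
                    g.add_edge((y, x), nb, weight=w)
    if g.number_of_nodes() < 2:
        return None
    return g


def _chain_length_um(path: List[Tuple[int, int]], dy_um: float,
                     dx_um: float) -> float:
    """Polyline length of a pixel chain, resampled to suppress staircase."""
    idx = list(range(0, len(path), _CHORD_STRIDE))
    if idx[-1] != len(path) - 1:
        idx.append(len(path) - 1)
    total = 0.0
    for i0, i1 in zip(idx[:-1], idx[1:]):
        (y0, x0), (y1, x1) = path[i0], path[i1]
        total += math.hypot((y1 - y0) * dy_um, (x1 - x0) * dx_um)
    return total


def _measure_segment(seg_mask: np.ndarray, dy_um: float, dx_um: float,
                     ) -> Optional[Tuple[float, float]]:
    """(geodesic length µm, chord angle degrees) of one in-plane segment.

    The root is the skeleton endpoint with the largest y (the apical end);
    the tip is the endpoint geodesically farthest from the root.
    """
    g = _skeleton_graph(seg_mask, dy_um, dx_um)
    if g is None:
        return None
    endpoints = [n for n, d in g.degree() if d == 1]
    if len(endpoints) < 2:
        return None
    root = max(endpoints, key=lambda p: (p[0], p[1]))
    dist, paths = nx.single_source_dijkstra(g, root, weight="weight")
    reachable = [e for e in endpoints if e != root and e in dist]
    if not reachable:
        return None
    tip = max(reachable, key=lambda e: dist[e])
    length = _chain_length_um(paths[tip], dy_um, dx_um)
    dx_phys = (tip[1] - root[1]) * dx_um
    dy_phys = (tip[0] - root[0]) * dy_um
    angle = math.degrees(math.atan2(-dy_phys, dx_phys))
    if angle < 0.0:
        angle += 180.0  # fold the degenerate "downward" chords (quantisation)
    return length, angle


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def microvillus_geometry(vol: LabelVolume, cell_id: str,
                         scheme: SamplingScheme,
                         ) -> Tuple[LinearMeasurementSet, LinearMeasurementSet]:
    """Microvillus length (µm) and tilt angle (degrees) for one cell.

    On every sampled slice the cell's in-plane microvillus segments
    (8-connected components) are identified; up to
    ``measurements_per_slice`` randomly chosen segments per slice are
    measured (length: skeleton geodesic; angle: root→tip chord against +x).
    """
    rng = np.random.default_rng(scheme.seed)
    mv_mask = compartment_mask(vol, cell_id, CompartmentKind.MICROVILLI)
    dy_um, dx_um = vol.spacing.dy * 1e-3, vol.spacing.dx * 1e-3
    lengths: List[float] = []
    angles: List[float] = []
    for z in scheme.slices(vol.n_slices):
        plane = mv_mask[z]
        if not plane.any():
            continue
        labelled, n = ndimage.label(plane, structure=np.ones((3, 3), bool))
        sizes = np.bincount(labelled.ravel())[1:]
        candidates = np.nonzero(sizes >= _MIN_SEGMENT_PIXELS)[0] + 1
        if candidates.size == 0:
            continue
        k = min(scheme.measurements_per_slice, candidates.size)
        chosen = rng.choice(candidates, size=k, replace=False)
        objects = ndimage.find_objects(labelled)
        for comp in chosen:
            sl = objects[comp - 1]
            res = _measure_segment(labelled[sl] == comp, dy_um, dx_um)
            if res is None:
                continue
            lengths.append(res[0])
            angles.append(res[1])
    if not lengths:
        raise ValueError(f"cell {cell_id!r}: no microvilli on any sampled slice")
    return (
        LinearMeasurementSet("microvillus_length", "um", np.array(lengths)),
        LinearMeasurementSet("microvillus_angle", "deg", np.array(angles)),
    )


def combined_height(body_height_mean_um: float,
                    microvillus_length_mean_um: float) -> float:
    """Total epithelium height: mean cell-body height plus mean microvillus
    length (an explicit sum of the two independently measured quantities)."""
    return body_height_mean_um + microvillus_length_mean_um


def rpe_height(vol: LabelVolume, cell_id: str, scheme: SamplingScheme,
               microvillus_length_mean_um: float | None = None,
               ) -> Tuple[LinearMeasurementSet, float]:
    """Cell-body height (µm, excluding microvilli) and combined height.

    Per sampled slice, ``measurements_per_slice`` random x-columns of the
    cell-body footprint are measured; a column's height is its y-extent
    times dy (organelle labels carved out of the body do not interrupt the
    extent).  The combined height adds the mean microvillus length, which
    is measured on the spot unless supplied.
    """
    rng = np.random.default_rng(scheme.seed)
    body = compartment_mask(vol, cell_id, CompartmentKind.CELL_BODY)
    dy_um = vol.spacing.dy * 1e-3
    heights: List[float] = []
    for z in scheme.slices(vol.n_slices):
        plane = body[z]
        cols = np.nonzero(plane.any(axis=0))[0]
        if cols.size == 0:
            continue
        k = min(scheme.measurements_per_slice, cols.size)
        for x in rng.choice(cols, size=k, replace=False):
            ys = np.nonzero(plane[:, x])[0]
            heights.append((ys[-1] - ys[0] + 1) * dy_um)
    if not heights:
        raise ValueError(f"cell {cell_id!r}: empty footprint on all sampled slices")
    body_set = LinearMeasurementSet("rpe_body_height", "um", np.array(heights))
    if microvillus_length_mean_um is None:
        mv_len, _ = microvillus_geometry(vol, cell_id, scheme)
        microvillus_length_mean_um = mv_len.mean
    return body_set, combined_height(body_set.mean, microvillus_length_mean_um)


def brm_thickness(vol: LabelVolume, scheme: SamplingScheme,
                  ) -> LinearMeasurementSet:
    """Bruch's-membrane thickness (nm) sampled under the cell footprints.

    Per sampled slice, ``measurements_per_slice`` seeded-random x-columns
    within the union cell-body footprint are probed; thickness is the
    contiguous BrM run length along y times dy.  Columns without BrM are
    skipped and logged, never zero-filled.
    """
    rng = np.random.default_rng(scheme.seed)
    brm_labels = vol.table.labels_for(kind=CompartmentKind.BRUCHS_MEMBRANE)
    if not brm_labels:
        raise ValueError("no bruchs_membrane labels in volume")
    brm = vol.label_mask(brm_labels)
    body_labels = [lab for cid in vol.table.cell_ids()
                   for lab in vol.table.labels_for(cid, CompartmentKind.CELL_BODY)]
    footprint = vol.label_mask(body_labels)
    samples: List[float] = []
    n_skipped = 0
    for z in scheme.slices(vol.n_slices):
        cols = np.nonzero(footprint[z].any(axis=0))[0]
        if cols.size == 0:
            continue
        k = min(scheme.measurements_per_slice, cols.size)
        for x in rng.choice(cols, size=k, replace=False):
            ys = np.nonzero(brm[z, :, x])[0]
            if ys.size == 0:
                n_skipped += 1
                continue
            # longest contiguous run (the slab is a single run by contract)
            breaks = np.nonzero(np.diff(ys) > 1)[0]
            runs = np.split(ys, breaks + 1)
            longest = max(runs, key=len)
            samples.append(len(longest) * vol.spacing.dy)
    if n_skipped:
        logger.info("brm_thickness: skipped %d columns without Bruch's "
                    "membrane", n_skipped)
    if not samples:
        raise ValueError("no Bruch's-membrane columns found under any cell")
    return LinearMeasurementSet("brm_thickness", "nm", np.array(samples))
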