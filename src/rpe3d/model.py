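"""Core data model for anisotropic 3D label volumes.

A segmented volume-EM scene is represented as a :class:`LabelVolume`: a 3D
integer grid indexed ``(z, y, x)`` (z = section index, y = the apical→basal
in-slice axis, x = the lateral in-slice axis), a :class:`VoxelSpacing` in
nanometres, and a :class:`LabelTable` mapping every positive label id to a
``(cell_id, compartment)`` pair.  Label 0 is reserved for background.

Orientation contract: apical structures (microvilli, photoreceptor outer
segments) face −y; Bruch's membrane lies at +y.  All downstream measurements
(heights, Bruch's-membrane thickness, basal thirds) rely on this convention.

Voxel spacing is always an explicit input and never read from TIFF metadata:
acquisition-time pixel sizes routinely stop being valid after downsampling,
so tag-derived spacing cannot be trusted for segmented exports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple, Union

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "CompartmentKind",
    "VoxelSpacing",
    "LabelTable",
    "LabelVolume",
    "read_label_stack",
    "write_label_stack",
    "compartment_mask",
]


class CompartmentKind(str, Enum):
    """Segmented compartment classes of the outer-retina scene."""

    CELL_BODY = "cell_body"
    NUCLEUS = "nucleus"
    MICROVILLI = "microvilli"
    BASAL_INFOLD_SPACE = "basal_infold_space"
    MITOCHONDRION = "mitochondrion"
    OUTER_SEGMENT = "outer_segment"
    BRUCHS_MEMBRANE = "bruchs_membrane"
    BACKGROUND = "background"


@dataclass(frozen=True)
class VoxelSpacing:
    """Anisotropic voxel spacing in nanometres.

    Parameters
    ----------
    dx, dy : float
        In-plane pixel width / height, nm.
    dz : float
        Section thickness, nm.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"VoxelSpacing.{name} must be positive, got {v!r}")

    @property
    def voxel_volume_nm3(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_volume_nm3 * 1e-9

    def face_areas_um2(self) -> Tuple[float, float, float]:
        """Voxel-face areas (z-facing, y-facing, x-facing) in µm²."""
        return (
            self.dx * self.dy * 1e-6,
            self.dx * self.dz * 1e-6,
            self.dy * self.dz * 1e-6,
        )


LabelEntry = Tuple[str, CompartmentKind]


@dataclass
class LabelTable:
    """Map from positive label id to ``(cell_id, compartment)``.

    Several labels may map to the same pair (e.g. two nucleus labels of a
    bi-nucleate cell); compartment masks are unions over matching labels.
    """

    entries: Dict[int, LabelEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[int, LabelEntry] = {}
        for label, (cell, kind) in self.entries.items():
            label = int(label)
            if label <= 0:
                raise ValueError(f"label ids must be positive, got {label}")
            clean[label] = (str(cell), CompartmentKind(kind))
        self.entries = clean

    def __contains__(self, label: int) -> bool:
        return int(label) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def cell_of(self, label: int) -> str:
        return self.entries[int(label)][0]

    def kind_of(self, label: int) -> CompartmentKind:
        return self.entries[int(label)][1]

    def labels_for(self, cell_id: str | None = None,
                   kind: CompartmentKind | None = None) -> List[int]:
        """Sorted label ids matching the given cell and/or compartment."""
        kind = CompartmentKind(kind) if kind is not None else None
        return sorted(
            lab for lab, (cell, k) in self.entries.items()
            if (cell_id is None or cell == str(cell_id))
            and (kind is None or k == kind)
        )

    def cell_ids(self) -> List[str]:
        """Sorted ids of cells owning at least one cell_body label."""
        return sorted({cell for cell, k in self.entries.values()
                       if k == CompartmentKind.CELL_BODY})

    def to_dict(self) -> dict:
        return {
            "labels": {
                str(lab): {"cell": cell, "compartment": kind.value}
                for lab, (cell, kind) in sorted(self.entries.items())
            }
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "LabelTable":
        entries = {
            int(lab): (rec["cell"], CompartmentKind(rec["compartment"]))
            for lab, rec in data.get("labels", {}).items()
        }
        return cls(entries)


@dataclass
class LabelVolume:
    """A 3D integer label grid with spacing and a label table.

    ``grid`` is indexed ``(z, y, x)``; labels are non-negative integers with
    0 = background.  Every non-zero label present in the grid must appear in
    ``table``.
    """

    grid: np.ndarray
    spacing: VoxelSpacing
    table: LabelTable

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D (z, y, x), got ndim={self.grid.ndim}")
        if self.grid.shape[0] < 1:
            raise ValueError("grid must contain at least one slice")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise TypeError(f"grid must be integer-typed, got {self.grid.dtype}")
        self.validate_labels()

    def validate_labels(self) -> None:
        present = self.present_labels()
        if present.size and present[0] < 0:
            raise ValueError("labels must be non-negative")
        unknown = [int(l) for l in present if l != 0 and l not in self.table]
        if unknown:
            raise ValueError(f"unknown label id(s) not in table: {unknown}")

    def present_labels(self) -> np.ndarray:
        return np.unique(self.grid)

    @property
    def n_slices(self) -> int:
        return self.grid.shape[0]

    def label_bbox(self, label: int, pad: int = 0):
        """Padded bounding-box slices of one label (None if absent).

        The underlying per-label bounding boxes are computed once per volume
        and cached; mutate ``grid`` through ``replace``-style copies, not in
        place, if you rely on them.
        """
        cache = self.__dict__.get("_bbox_cache")
        if cache is None:
            cache = ndimage.find_objects(self.grid)
            self.__dict__["_bbox_cache"] = cache
        label = int(label)
        if label < 1 or label > len(cache) or cache[label - 1] is None:
            return None
        return tuple(
            slice(max(0, s.start - pad), min(n, s.stop + pad))
            for s, n in zip(cache[label - 1], self.grid.shape)
        )

    def label_mask(self, labels: Union[int, Iterable[int]]) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given labels."""
        if np.isscalar(labels):
            return self.grid == int(labels)
        labels = list(labels)
        if not labels:
            return np.zeros(self.grid.shape, dtype=bool)
        return np.isin(self.grid, np.asarray(labels, dtype=self.grid.dtype))


def compartment_mask(vol: LabelVolume, cell_id: str,
                     kind: CompartmentKind) -> np.ndarray:
    """Boolean mask of one cell's compartment (union over matching labels).

    A missing compartment (e.g. a cell generated without basal infold
    pockets) yields an empty mask with a warning rather than an error.
    """
    labels = vol.table.labels_for(cell_id, kind)
    if not labels:
        warnings.warn(
            f"no label maps to cell {cell_id!r} / {CompartmentKind(kind).value}; "
            "returning an empty mask",
            stacklevel=2,
        )
    return vol.label_mask(labels)


def _smallest_uint_dtype(max_label: int) -> np.dtype:
    for dt in (np.uint8, np.uint16, np.uint32):
        if max_label <= np.iinfo(dt).max:
            return np.dtype(dt)
    return np.dtype(np.uint64)


def write_label_stack(vol: LabelVolume, path: Union[str, Path],
                      table_path: Union[str, Path, None] = None) -> None:
    """Write a LabelVolume as a multi-page unsigned-integer TIFF.

    The round trip through :func:`read_label_stack` is lossless on the grid.
    If ``table_path`` is given, the label table plus spacing are written there
    as JSON (schema: ``{"labels": {...}, "spacing_nm": [dz, dy, dx]}``).
    """
    max_label = int(vol.grid.max(initial=0))
    data = vol.grid.astype(_smallest_uint_dtype(max_label), copy=False)
    tifffile.imwrite(str(path), data, photometric="minisblack")
    if table_path is not None:
        doc = vol.table.to_dict()
        doc["spacing_nm"] = [vol.spacing.dz, vol.spacing.dy, vol.spacing.dx]
        Path(table_path).write_text(json.dumps(doc, indent=1))


def read_label_stack(path: Union[str, Path],
                     spacing: VoxelSpacing | None = None,
                     table_path: Union[str, Path, None] = None,
                     table: LabelTable | None = None) -> LabelVolume:
    """Read a multi-page integer TIFF label stack into a LabelVolume.

    Spacing must be supplied, either explicitly via ``spacing`` (nm) or via
    the ``spacing_nm`` field of the JSON label table; an explicit argument
    wins.  Raises on non-integer pixel data, inconsistent page shapes, or
    labels absent from the table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise ValueError(f"{path}: empty TIFF")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"{path}: inconsistent page shapes {sorted(shapes)}")
    grid = np.stack(pages, axis=0)
    if grid.ndim != 3:
        raise ValueError(f"{path}: expected single-channel pages, got shape {grid.shape}")
    if not np.issubdtype(grid.dtype, np.integer):
        raise TypeError(f"{path}: non-integer pixel data ({grid.dtype})")

    if table is None:
        if table_path is None:
            raise ValueError("a label table (table= or table_path=) is required")
        doc = json.loads(Path(table_path).read_text())
        table = LabelTable.from_dict(doc)
        if spacing is None and "spacing_nm" in doc:
            dz, dy, dx = doc["spacing_nm"]
            spacing = VoxelSpacing(dx=dx, dy=dy, dz=dz)
    if spacing is None:
        raise ValueError(
            "voxel spacing must be supplied explicitly (argument or JSON "
            "'spacing_nm'); it is never inferred from TIFF tags"
        )
    return LabelVolume(grid=grid, spacing=spacing, table=table)
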