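"""Left-ventricular short-axis geometry: contours, myocardial masks and the AHA model.

The geometric substrate is a stack of short-axis slices, each carrying an
endocardial and an epicardial contour (polygons with vertices in mm, in the
image coordinate frame).  Pixels live on a row-major grid; the centre of pixel
``(row, col)`` is at ``x = (col + 0.5) * dx``, ``y = (row + 0.5) * dy``.

Regional reporting uses the standard AHA division of the left ventricle:
6 basal, 6 mid-cavity and 4 apical sectors plus the apical cap (segment 17).
Angles are measured counterclockwise from the anterior RV insertion point,
which is a required input (``rv_insertion_angle``, radians from the image +x
axis about the endocardial centroid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import GeometryError, MappingError

BASAL = "basal"
MID = "mid"
APICAL = "apical"
LEVELS = (BASAL, MID, APICAL)

#: number of angular sectors per level (the cap is not an angular sector)
SECTOR_COUNT = {BASAL: 6, MID: 6, APICAL: 4}
#: first segment ID of each level
SEGMENT_BASE = {BASAL: 1, MID: 7, APICAL: 13}
#: chord-level transmurality is defined for the 16 sectoral segments only
SECTORAL_SEGMENTS = tuple(range(1, 17))
APEX_CAP_SEGMENT = 17

MYOCARDIAL_DENSITY_G_PER_CM3 = 1.05


def _as_ring(vertices) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise GeometryError("a contour needs an (N, 2) array with N >= 3 vertices")
    return arr


@dataclass
class SliceGeometry:
    """One short-axis slice: endo/epi contours plus grid metadata.

    Parameters
    ----------
    z_index : int
        Slice order, 0 = most basal; strictly increasing toward the apex.
    endo, epi : (N, 2) arrays
        Closed simple polygons in mm (last vertex need not repeat the first).
    pixel_spacing : (dx, dy)
        Pixel size in mm.
    slice_span : float
        Slice thickness plus gap in mm (the through-plane extent attributed
        to this slice).
    grid_shape : (rows, cols)
        Shape of the co-registered raster grid.
    """

    z_index: int
    endo: np.ndarray
    epi: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_span: float
    grid_shape: tuple[int, int]
    _endo_poly: Polygon = field(init=False, repr=False, default=None)
    _epi_poly: Polygon = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.endo = _as_ring(self.endo)
        self.epi = _as_ring(self.epi)
        dx, dy = self.pixel_spacing
        if dx <= 0 or dy <= 0:
            raise GeometryError(f"slice {self.z_index}: pixel_spacing must be positive")
        if self.slice_span <= 0:
            raise GeometryError(f"slice {self.z_index}: slice_span must be positive")
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise GeometryError(f"slice {self.z_index}: grid_shape must be positive")
        self._endo_poly = Polygon(self.endo)
        self._epi_poly = Polygon(self.epi)
        for name, poly in (("endo", self._endo_poly), ("epi", self._epi_poly)):
            if not poly.is_valid:
                raise GeometryError(f"slice {self.z_index}: {name} polygon is not simple")
        if self._epi_poly.difference(self._endo_poly).area <= 0:
            raise GeometryError(
                f"slice {self.z_index}: zero-thickness wall (endo does not leave room inside epi)"
            )
        if not self._epi_poly.covers(self._endo_poly):
            raise GeometryError(f"slice {self.z_index}: endo polygon not inside epi polygon")

    @property
    def endo_polygon(self) -> Polygon:
        return self._endo_poly

    @property
    def epi_polygon(self) -> Polygon:
        return self._epi_poly

    @property
    def centroid(self) -> np.ndarray:
        """LV centre of this slice: centroid of the endocardial polygon (mm)."""
        c = self._endo_poly.centroid
        return np.array([c.x, c.y])

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_area_mm2 * self.slice_span

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of pixel-centre coordinates in mm, shape = grid_shape."""
        rows, cols = self.grid_shape
        dx, dy = self.pixel_spacing
        x = (np.arange(cols) + 0.5) * dx
        y = (np.arange(rows) + 0.5) * dy
        return np.meshgrid(x, y)


@dataclass
class ContourStack:
    """Ordered basal-to-apical collection of slices plus the angular reference."""

    slices: list[SliceGeometry]
    rv_insertion_angle: float = 0.0

    def __post_init__(self):
        if not self.slices:
            raise GeometryError("a ContourStack needs at least one slice")
        z = [s.z_index for s in self.slices]
        if any(b <= a for a, b in zip(z, z[1:])):
            raise GeometryError("z_index must be strictly increasing basal to apical")

    def __len__(self) -> int:
        return len(self.slices)


def assign_levels(stack: ContourStack | int) -> dict[int, str]:
    """Partition slices into contiguous basal/mid/apical thirds by count.

    The remainder is distributed basal-first, then mid, so e.g. 11 slices give
    4 basal, 4 mid and 3 apical.  Raises :class:`MappingError` below 3 slices.
    """
    if isinstance(stack, int):
        n = stack
        zs = list(range(n))
    else:
        n = len(stack)
        zs = [s.z_index for s in stack.slices]
    if n < 3:
        raise MappingError(f"AHA level assignment needs >= 3 slices, got {n}")
    base, rem = divmod(n, 3)
    counts = [base + (1 if rem >= 1 else 0), base + (1 if rem >= 2 else 0), base]
    mapping: dict[int, str] = {}
    i = 0
    for level, c in zip(LEVELS, counts):
        for _ in range(c):
            mapping[zs[i]] = level
            i += 1
    return mapping


def segment_id(level: str, angle: float, rv_insertion_angle: float) -> int:
    """AHA segment ID (1-16) for an angle at a given level.

    Angles are measured counterclockwise from ``rv_insertion_angle``; sectors
    are half-open ``[start, end)`` so every angle maps to exactly one segment.
    """
    if level not in SECTOR_COUNT:
        raise MappingError(f"unknown AHA level {level!r}")
    nsec = SECTOR_COUNT[level]
    rel = (angle - rv_insertion_angle) % (2.0 * math.pi)
    k = int(rel / (2.0 * math.pi / nsec))
    return SEGMENT_BASE[level] + min(k, nsec - 1)


def sector_bounds(level: str, rv_insertion_angle: float) -> list[tuple[int, float, float]]:
    """Absolute angular bounds [start, end) of each sector of a level."""
    nsec = SECTOR_COUNT[level]
    width = 2.0 * math.pi / nsec
    return [
        (SEGMENT_BASE[level] + k, rv_insertion_angle + k * width, rv_insertion_angle + (k + 1) * width)
        for k in range(nsec)
    ]


def rasterize_myocardium(sl: SliceGeometry) -> np.ndarray:
    """Boolean myocardium mask: pixel centres inside epi and outside-or-on endo."""
    X, Y = sl.pixel_centers()
    inside_epi = shapely.contains_xy(sl.epi_polygon, X.ravel(), Y.ravel())
    inside_endo = shapely.contains_xy(sl.endo_polygon, X.ravel(), Y.ravel())
    mask = (inside_epi & ~inside_endo).reshape(sl.grid_shape)
    if not mask.any():
        raise GeometryError(
            f"slice {sl.z_index}: empty myocardium mask (wall thinner than the pixel grid?)"
        )
    return mask


@dataclass
class MyocardiumMask:
    """Per-slice myocardium rasters, co-registered with a :class:`ContourStack`."""

    masks: list[np.ndarray]

    @classmethod
    def from_stack(cls, stack: ContourStack) -> "MyocardiumMask":
        return cls([rasterize_myocardium(s) for s in stack.slices])

    def __iter__(self):
        return iter(self.masks)

    def __getitem__(self, i):
        return self.masks[i]

    def __len__(self):
        return len(self.masks)


def segment_label_map(sl: SliceGeometry, level: str, rv_insertion_angle: float,
                      myo: np.ndarray | None = None) -> np.ndarray:
    """Integer segment labels per pixel (0 outside the myocardium)."""
    if myo is None:
        myo = rasterize_myocardium(sl)
    X, Y = sl.pixel_centers()
    cx, cy = sl.centroid
    ang = np.arctan2(Y - cy, X - cx)
    nsec = SECTOR_COUNT[level]
    width = 2.0 * math.pi / nsec
    rel = np.mod(ang - rv_insertion_angle, 2.0 * math.pi)
    k = np.minimum((rel / width).astype(int), nsec - 1)
    labels = np.where(myo, SEGMENT_BASE[level] + k, 0)
    return labels


def lv_mass(stack: ContourStack, myo: MyocardiumMask | None = None) -> float:
    """LV myocardial mass in grams (1.05 g/cm^3, summed voxel volumes)."""
    if myo is None:
        myo = MyocardiumMask.from_stack(stack)
    volume_mm3 = sum(
        int(m.sum()) * s.voxel_volume_mm3 for s, m in zip(stack.slices, myo.masks)
    )
    return MYOCARDIAL_DENSITY_G_PER_CM3 * volume_mm3 / 1000.0


@dataclass
class AHAModel:
    """Mapping from (slice, angle) to AHA segment IDs for one stack."""

    level_of_slice: dict[int, str]
    rv_insertion_angle: float

    @classmethod
    def from_stack(cls, stack: ContourStack) -> "AHAModel":
        return cls(assign_levels(stack), stack.rv_insertion_angle)

    def segment_of(self, z_index: int, angle: float) -> int:
        return segment_id(self.level_of_slice[z_index], angle, self.rv_insertion_angle)

    def slices_of_level(self, level: str) -> list[int]:
        return [z for z, lv in self.level_of_slice.items() if lv == level]

    @property
    def apical_z(self) -> int:
        """z_index of the most apical slice (used for the segment-17 scar flag)."""
        return max(self.level_of_slice)
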