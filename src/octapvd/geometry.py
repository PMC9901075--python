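"""Scan coordinate system, optic-disc ellipse, ring ROI and quadrant sectors.

The measurement region for peripapillary vessel density is a 750 µm-wide
elliptical ring immediately outside the optic-disc boundary.  The ring is
built as a constant-width outward offset of the disc region (Euclidean
distance transform), which keeps the band width uniform along the boundary —
a concentric scaled ellipse would not.  The ring is then split into the four
standard peripapillary quadrants (superior / inferior / nasal / temporal) by
the ±45° diagonals through the ellipse center; the nasal/temporal assignment
depends on eye laterality.

Conventions
-----------
* image coordinates are 0-based ``(row, col)``; row 0 is the top edge and is
  superior by default;
* all physical quantities are in micrometres (µm);
* for a right eye (OD) in standard en-face orientation the nasal side is the
  image-right edge (higher column index); for a left eye (OS) it is the
  image-left edge.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel


class Laterality(str, Enum):
    OD = "OD"  # right eye
    OS = "OS"  # left eye


class Sector(str, Enum):
    SUPERIOR = "superior"
    INFERIOR = "inferior"
    NASAL = "nasal"
    TEMPORAL = "temporal"


#: integer codes used in the sector label raster (0 = outside the ring)
SECTOR_CODES = {
    Sector.SUPERIOR: 1,
    Sector.INFERIOR: 2,
    Sector.NASAL: 3,
    Sector.TEMPORAL: 4,
}


class GeometryError(ValueError):
    """Invalid geometric input (degenerate fit, empty ROI, ...)."""


class EllipseFitError(GeometryError):
    """Ellipse fit failed: too few or degenerate boundary points."""


class AmbiguousMaskError(GeometryError):
    """Disc mask contains several connected components; select one."""


class EmptyRoiError(GeometryError):
    """The requested ring ROI contains no in-image pixels."""


@dataclass(frozen=True)
class ScanGrid:
    """Pixel raster of one en-face scan plus its physical extent.

    The default 6×6 mm field matches a disc-centred swept-source OCTA scan.
    Pixel spacing may be anisotropic; all distance computations carry the
    per-axis µm/px sampling.
    """

    rows: int
    cols: int
    scan_width_mm: float = 6.0
    scan_height_mm: float = 6.0
    laterality: Laterality = Laterality.OD

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise GeometryError("grid must have positive pixel dimensions")
        if not (self.scan_width_mm > 0 and self.scan_height_mm > 0):
            raise GeometryError("scan extent must be positive")
        object.__setattr__(self, "laterality", Laterality(self.laterality))

    @property
    def um_per_px_col(self) -> float:
        return self.scan_width_mm * 1000.0 / self.cols

    @property
    def um_per_px_row(self) -> float:
        return self.scan_height_mm * 1000.0 / self.rows

    @property
    def sampling(self) -> tuple[float, float]:
        """(row, col) µm/px sampling for scipy distance transforms."""
        return (self.um_per_px_row, self.um_per_px_col)

    @property
    def px_area_um2(self) -> float:
        return self.um_per_px_row * self.um_per_px_col

    def with_laterality(self, laterality: Laterality | str) -> "ScanGrid":
        return ScanGrid(self.rows, self.cols, self.scan_width_mm,
                        self.scan_height_mm, Laterality(laterality))


@dataclass(frozen=True)
class DiscEllipse:
    """Optic-disc boundary ellipse.

    ``center_row``/``center_col`` are subpixel image coordinates; the semi
    axes are physical lengths in µm with ``semi_axis_a >= semi_axis_b``;
    ``rotation`` is the angle (radians) of the major axis from the image +x
    (column) axis toward +y (row, i.e. downward), in physical µm space.
    """

    center_row: float
    center_col: float
    semi_axis_a_um: float
    semi_axis_b_um: float
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if not (self.semi_axis_a_um >= self.semi_axis_b_um > 0):
            raise GeometryError(
                "ellipse axes must satisfy a >= b > 0 "
                f"(got a={self.semi_axis_a_um}, b={self.semi_axis_b_um})")

    def area_um2(self) -> float:
        return math.pi * self.semi_axis_a_um * self.semi_axis_b_um

    def perimeter_um(self) -> float:
        # Ramanujan's second approximation
        a, b = self.semi_axis_a_um, self.semi_axis_b_um
        h = (a - b) ** 2 / (a + b) ** 2
        return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))

    def interior_mask(self, grid: ScanGrid) -> np.ndarray:
        """Boolean raster of the disc interior on ``grid``."""
        return self._interior(grid, row_offset=0, col_offset=0,
                              shape=(grid.rows, grid.cols))

    def _interior(self, grid: ScanGrid, row_offset: int, col_offset: int,
                  shape: tuple[int, int]) -> np.ndarray:
        rr = (np.arange(shape[0]) + row_offset) * grid.um_per_px_row
        cc = (np.arange(shape[1]) + col_offset) * grid.um_per_px_col
        dy = rr[:, None] - self.center_row * grid.um_per_px_row
        dx = cc[None, :] - self.center_col * grid.um_per_px_col
        ct, st = math.cos(self.rotation), math.sin(self.rotation)
        x_maj = ct * dx + st * dy
        y_min = -st * dx + ct * dy
        return (x_maj / self.semi_axis_a_um) ** 2 + \
               (y_min / self.semi_axis_b_um) ** 2 <= 1.0


@dataclass(frozen=True)
class RingRoiMask:
    """Ring-shaped measurement region outside the disc.

    ``clipped_fraction`` is the fraction of the ideal (unclipped) ring lost
    to the image borders; densities downstream are computed on the pixels
    that remain.
    """

    mask: np.ndarray
    width_um: float
    source_ellipse: DiscEllipse
    clipped_fraction: float = 0.0

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    def area_um2(self, grid: ScanGrid) -> float:
        return self.pixel_count * grid.px_area_um2


@dataclass(frozen=True)
class SectorLabels:
    """Per-pixel quadrant labels over the ring.

    ``labels`` holds SECTOR_CODES values on ring pixels and 0 elsewhere.
    Boundary convention: angles measured from the image-right axis with
    superior up; superior = [45°, 135°), inferior = [225°, 315°); the two
    lateral wedges map to nasal/temporal according to laterality.  Intervals
    are half-open, so boundary pixels have a deterministic label.
    """

    labels: np.ndarray
    laterality: Laterality
    convention: str = ("theta=atan2(-d_row_um, d_col_um); superior=[45,135), "
                       "inferior=[225,315); OD nasal = image right")

    def mask(self, sector: Sector) -> np.ndarray:
        return self.labels == SECTOR_CODES[Sector(sector)]

    def counts(self) -> dict[Sector, int]:
        return {s: int((self.labels == c).sum()) for s, c in SECTOR_CODES.items()}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def fit_disc_ellipse(boundary_points: np.ndarray | None = None,
                     disc_mask: np.ndarray | None = None,
                     grid: ScanGrid | None = None) -> DiscEllipse:
    """Least-squares ellipse fit of the (manually delineated) disc boundary.

    Exactly one of ``boundary_points`` (N×2 subpixel ``(row, col)``) or
    ``disc_mask`` (boolean raster, single connected component of >= 20 px)
    must be given.  Points are fitted in physical µm coordinates so that
    anisotropic pixels are handled; the returned axes are in µm.
    """
    if grid is None:
        raise GeometryError("a ScanGrid is required to convert to µm")
    if (boundary_points is None) == (disc_mask is None):
        raise GeometryError("provide either boundary_points or disc_mask")

    if disc_mask is not None:
        mask = np.asarray(disc_mask, dtype=bool)
        lab, n = ndimage.label(mask)
        if n == 0 or mask.sum() < 20:
            raise EllipseFitError("disc mask must contain >= 20 pixels")
        if n > 1:
            raise AmbiguousMaskError(
                f"disc mask has {n} connected components; pass a single one")
        boundary = mask & ~ndimage.binary_erosion(mask)
        boundary_points = np.argwhere(boundary).astype(float)

    pts = np.asarray(boundary_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise EllipseFitError(">= 5 (row, col) boundary points required")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise EllipseFitError("boundary points are collinear")

    xy = np.column_stack([pts[:, 1] * grid.um_per_px_col,
                          pts[:, 0] * grid.um_per_px_row])
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(xy)
        ok = bool(model)
    else:  # skimage < 0.26
        model = EllipseModel()
        ok = model.estimate(xy)
    if not ok:
        raise EllipseFitError("ellipse fit did not converge")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise EllipseFitError("ellipse fit did not converge")
    if b > a:
        a, b = b, a
        theta += math.pi / 2
    theta = math.remainder(theta, math.pi)

    ellipse = DiscEllipse(center_row=yc / grid.um_per_px_row,
                          center_col=xc / grid.um_per_px_col,
                          semi_axis_a_um=a, semi_axis_b_um=b,
                          rotation=theta)
    if not (0 <= ellipse.center_row < grid.rows
            and 0 <= ellipse.center_col < grid.cols):
        warnings.warn("fitted disc center lies outside the image",
                      stacklevel=2)
    return ellipse


def build_ring_roi(ellipse: DiscEllipse, grid: ScanGrid,
                   width_um: float = 750.0) -> RingRoiMask:
    """Constant-width outward offset ring around the disc region.

    A pixel belongs to the ring iff its Euclidean distance (µm) to the
    rasterized disc region is in ``(0, width_um]``.  The offset is computed
    on a padded canvas so the fraction of the ideal ring clipped by the image
    borders can be reported exactly.
    """
    if width_um < 0:
        raise GeometryError("width_um must be >= 0")
    if width_um == 0:
        empty = np.zeros((grid.rows, grid.cols), dtype=bool)
        return RingRoiMask(mask=empty, width_um=0.0, source_ellipse=ellipse)

    pad_r = int(math.ceil(width_um / grid.um_per_px_row)) + 2
    pad_c = int(math.ceil(width_um / grid.um_per_px_col)) + 2
    shape = (grid.rows + 2 * pad_r, grid.cols + 2 * pad_c)
    disc_pad = ellipse._interior(grid, row_offset=-pad_r, col_offset=-pad_c,
                                 shape=shape)
    if not disc_pad.any():
        raise EmptyRoiError("disc ellipse rasterizes to no pixels")

    dist = ndimage.distance_transform_edt(~disc_pad, sampling=grid.sampling)
    ring_pad = (dist > 0) & (dist <= width_um)
    ring = ring_pad[pad_r:pad_r + grid.rows, pad_c:pad_c + grid.cols]
    total = int(ring_pad.sum())
    kept = int(ring.sum())
    if kept == 0:
        raise EmptyRoiError("ring ROI lies entirely outside the image")
    clipped = 1.0 - kept / total if total else 1.0
    if clipped > 0:
        warnings.warn(f"{clipped:.1%} of the ring ROI is clipped by the "
                      "image borders", stacklevel=2)
    return RingRoiMask(mask=ring, width_um=float(width_um),
                       source_ellipse=ellipse, clipped_fraction=clipped)


def sectorize(roi: RingRoiMask, ellipse: DiscEllipse,
              grid: ScanGrid) -> SectorLabels:
    """Label every ring pixel with its peripapillary quadrant.

    The angle of the ray from the ellipse center is measured in physical µm
    space from the image-right axis, counter-clockwise with superior up
    (i.e. ``atan2(-d_row, d_col)``).
    """
    if not roi.mask.any():
        raise EmptyRoiError("cannot sectorize an empty ring ROI")
    rows, cols = np.nonzero(roi.mask)
    dy = (rows - ellipse.center_row) * grid.um_per_px_row
    dx = (cols - ellipse.center_col) * grid.um_per_px_col
    theta = np.degrees(np.arctan2(-dy, dx)) % 360.0

    labels = np.zeros(roi.mask.shape, dtype=np.uint8)
    sup = (theta >= 45.0) & (theta < 135.0)
    inf = (theta >= 225.0) & (theta < 315.0)
    right = (theta >= 315.0) | (theta < 45.0)
    left = (theta >= 135.0) & (theta < 225.0)

    if grid.laterality is Laterality.OD:
        nasal, temporal = right, left
    else:
        nasal, temporal = left, right

    labels[rows[sup], cols[sup]] = SECTOR_CODES[Sector.SUPERIOR]
    labels[rows[inf], cols[inf]] = SECTOR_CODES[Sector.INFERIOR]
    labels[rows[nasal], cols[nasal]] = SECTOR_CODES[Sector.NASAL]
    labels[rows[temporal], cols[temporal]] = SECTOR_CODES[Sector.TEMPORAL]
    return SectorLabels(labels=labels, laterality=grid.laterality)
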