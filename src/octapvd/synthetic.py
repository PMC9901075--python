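"""Synthetic en-face angiograms and longitudinal cohorts with ground truth.

No public OCTA dataset accompanies this kind of peripapillary study, so the
package ships two seeded generators:

``generate_angiogram``
    renders a disc-centred en-face scene — dark optic disc, bright large
    vessels radiating from the disc rim, a fine capillary texture whose
    per-quadrant coverage inside the ring ROI is tuned to a requested target
    fraction, multiplicative speckle, a global signal-strength scaling and
    optional zeroed shadow-artifact patches — together with the exact
    ground-truth masks and per-sector perfusion fractions (pixel counts on
    the noise-free masks).

``generate_cohort``
    draws per-eye, per-visit, per-slab, per-quadrant vessel densities from
    an additive random-intercept model
    ``pvd = mu[sector,slab] + delta[sector,visit,slab] + gamma*1[DR, post-op,
    DCP] + b_eye + noise`` — the minimal structure a repeated-measures
    ANOVA assumes — mimicking a 33-eye surgical cohort with sector-specific
    post-operative declines and a diabetic-retinopathy deficit in the deep
    plexus.

Background (no-flow) pixels have intensity exactly zero and the speckle is
purely multiplicative, so a scene without vasculature stays blank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import (DiscEllipse, RingRoiMask, ScanGrid, Sector,
                       SectorLabels, build_ring_roi, sectorize)
from .perfusion import EnFaceAngiogram, Slab

# rendered intensities of the noise-free scene (arbitrary device units)
BACKGROUND_LEVEL = 0.0
DISC_LEVEL = 0.05
CAPILLARY_LEVEL = 0.80
LARGE_VESSEL_LEVEL = 0.95

#: capillary structures are kept thinner than this caliber (µm) so that the
#: large-vessel caliber filter (default cutoff 30 µm) never captures them
MAX_CAPILLARY_CALIBER_UM = 25.0

VISITS = ("baseline", "6mo", "12mo")
SECTOR_ORDER = (Sector.SUPERIOR, Sector.TEMPORAL, Sector.INFERIOR,
                Sector.NASAL)


class SceneConfigError(ValueError):
    pass


def _default_capillary_fractions() -> dict[str, float]:
    return {Sector.SUPERIOR.value: 0.52, Sector.TEMPORAL.value: 0.48,
            Sector.INFERIOR.value: 0.55, Sector.NASAL.value: 0.50}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic angiogram scene (seed-deterministic)."""

    grid: ScanGrid = field(default_factory=lambda: ScanGrid(1024, 1024))
    disc_semi_axis_a_um: float = 950.0
    disc_semi_axis_b_um: float = 800.0
    disc_rotation: float = 0.0
    ring_width_um: float = 750.0
    n_large_vessels: int = 8
    large_vessel_width_range_um: tuple[float, float] = (40.0, 120.0)
    capillary_target_fraction: dict[str, float] | float = field(
        default_factory=_default_capillary_fractions)
    speckle_shape: float | None = 25.0  # gamma shape k; None = noise-free
    signal_strength: int = 9
    artifact_patches: int = 0
    artifact_size_range_um: tuple[float, float] = (300.0, 800.0)
    seed: int = 0

    def sector_targets(self) -> dict[str, float]:
        t = self.capillary_target_fraction
        if np.isscalar(t):
            targets = {s.value: float(t) for s in Sector}
        else:
            targets = {Sector(k).value: float(v) for k, v in dict(t).items()}
            missing = {s.value for s in Sector} - set(targets)
            if missing:
                raise SceneConfigError(f"missing sector targets: {missing}")
        for name, f in targets.items():
            if not 0.0 <= f <= 1.0:
                raise SceneConfigError(f"target fraction {name}={f} not in [0,1]")
            if f > 0.95:
                raise SceneConfigError(
                    f"target fraction {name}={f} > 0.95 is unreachable for a "
                    "thin-curve capillary texture")
        return targets

    def disc_ellipse(self) -> DiscEllipse:
        return DiscEllipse(center_row=(self.grid.rows - 1) / 2.0,
                           center_col=(self.grid.cols - 1) / 2.0,
                           semi_axis_a_um=self.disc_semi_axis_a_um,
                           semi_axis_b_um=self.disc_semi_axis_b_um,
                           rotation=self.disc_rotation)


@dataclass(frozen=True)
class GroundTruth:
    """Exact masks and pixel-count fractions behind one synthetic scene."""

    perfusion_mask: np.ndarray       # capillaries ∪ large vessels
    capillary_mask: np.ndarray
    vessel_mask: np.ndarray
    disc_mask: np.ndarray
    artifact_mask: np.ndarray
    ring: RingRoiMask
    sectors: SectorLabels
    disc: DiscEllipse
    sector_fractions: dict[str, float]
    sector_measured_px: dict[str, int]

    @property
    def mean_fraction(self) -> float:
        num = sum(self.sector_fractions[s.value] * self.sector_measured_px[s.value]
                  for s in Sector)
        den = sum(self.sector_measured_px.values())
        return num / den if den else float("nan")


# ---------------------------------------------------------------------------
# angiogram generator
# ---------------------------------------------------------------------------

def _trace_vessel(rng: np.random.Generator, start: np.ndarray, heading: float,
                  shape: tuple[int, int]) -> np.ndarray:
    """Random-walk centreline from the disc rim to the image border (px)."""
    max_steps = int(1.2 * (shape[0] + shape[1]))
    turns = rng.normal(0.0, 0.08, size=max_steps)
    curvature = rng.normal(0.0, 0.002)
    headings = heading + np.cumsum(turns) + curvature * np.arange(max_steps)
    step = 3.0
    drc = np.column_stack([-np.sin(headings), np.cos(headings)]) * step
    path = start[None, :] + np.cumsum(drc, axis=0)
    inside = ((path[:, 0] >= -2) & (path[:, 0] < shape[0] + 2)
              & (path[:, 1] >= -2) & (path[:, 1] < shape[1] + 2))
    stop = np.argmin(inside) if not inside.all() else max_steps
    return path[:max(stop, 2)]


def _stamp_tube(mask: np.ndarray, path: np.ndarray, half_width_um: float,
                grid: ScanGrid) -> None:
    """Thicken a polyline to a tube of the given half width (µm), in place."""
    rr = np.clip(np.round(path[:, 0]).astype(int), 0, mask.shape[0] - 1)
    cc = np.clip(np.round(path[:, 1]).astype(int), 0, mask.shape[1] - 1)
    mr = int(math.ceil(half_width_um / grid.um_per_px_row)) + 2
    mc = int(math.ceil(half_width_um / grid.um_per_px_col)) + 2
    r0, r1 = max(rr.min() - mr, 0), min(rr.max() + mr + 1, mask.shape[0])
    c0, c1 = max(cc.min() - mc, 0), min(cc.max() + mc + 1, mask.shape[1])
    local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    local[rr - r0, cc - c0] = True
    dist = ndimage.distance_transform_edt(~local, sampling=grid.sampling)
    mask[r0:r1, c0:c1] |= dist <= half_width_um


def _draw_large_vessels(rng: np.random.Generator, config: SceneConfig,
                        disc: DiscEllipse) -> np.ndarray:
    grid = config.grid
    mask = np.zeros((grid.rows, grid.cols), dtype=bool)
    n = config.n_large_vessels
    lo, hi = config.large_vessel_width_range_um
    for i in range(n):
        phi = 2 * math.pi * (i + rng.uniform(-0.25, 0.25)) / n
        # rim point of the ellipse at parameter phi, in pixel coordinates
        ex = disc.semi_axis_a_um * math.cos(phi)
        ey = disc.semi_axis_b_um * math.sin(phi)
        ct, st = math.cos(disc.rotation), math.sin(disc.rotation)
        dx, dy = ct * ex - st * ey, st * ex + ct * ey
        start = np.array([disc.center_row + dy / grid.um_per_px_row,
                          disc.center_col + dx / grid.um_per_px_col])
        heading = math.atan2(-dy, dx)  # outward, superior-up angle
        path = _trace_vessel(rng, start, heading, mask.shape)
        width = rng.uniform(lo, hi)
        _stamp_tube(mask, path, width / 2.0, grid)
    return mask


def _prune_thick(cap: np.ndarray, grid: ScanGrid) -> np.ndarray:
    """Remove capillary pixels whose local caliber exceeds the cap."""
    if not cap.any():
        return cap
    radius = ndimage.distance_transform_edt(cap, sampling=grid.sampling)
    return cap & (2.0 * radius <= MAX_CAPILLARY_CALIBER_UM)


def _prune_thick_region(cap: np.ndarray, grid: ScanGrid,
                        bbox: tuple[int, int, int, int]) -> None:
    """Prune only inside ``bbox`` (in place), with enough margin around the
    window that the distance transform is exact for every updated pixel."""
    r0, r1, c0, c1 = bbox
    mr = int(math.ceil(MAX_CAPILLARY_CALIBER_UM / 2 / grid.um_per_px_row)) + 2
    mc = int(math.ceil(MAX_CAPILLARY_CALIBER_UM / 2 / grid.um_per_px_col)) + 2
    er0, er1 = max(r0 - mr, 0), min(r1 + mr, cap.shape[0])
    ec0, ec1 = max(c0 - mc, 0), min(c1 + mc, cap.shape[1])
    sub = cap[er0:er1, ec0:ec1]
    if not sub.any():
        return
    radius = ndimage.distance_transform_edt(sub, sampling=grid.sampling)
    keep = 2.0 * radius <= MAX_CAPILLARY_CALIBER_UM
    cap[r0:r1, c0:c1] &= keep[r0 - er0:r1 - er0, c0 - ec0:c1 - ec0]


def _capillary_curve(rng: np.random.Generator, start: np.ndarray) -> np.ndarray:
    n_steps = int(rng.integers(12, 30))
    headings = rng.uniform(0, 2 * math.pi) + np.cumsum(
        rng.normal(0.0, 0.35, size=n_steps))
    drc = np.column_stack([-np.sin(headings), np.cos(headings)]) * 1.6
    return start[None, :] + np.cumsum(drc, axis=0)


_STAMP_OFFSETS = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])


def _fill_sector_capillaries(rng: np.random.Generator, cap: np.ndarray,
                             allowed: np.ndarray, target_px: int,
                             grid: ScanGrid) -> None:
    """Grow thin random curves inside ``allowed`` until close to target."""
    allowed_idx = np.argwhere(allowed)
    if len(allowed_idx) == 0:
        return
    bbox = (int(allowed_idx[:, 0].min()), int(allowed_idx[:, 0].max()) + 1,
            int(allowed_idx[:, 1].min()), int(allowed_idx[:, 1].max()) + 1)
    # ~12 µm-wide curves: a 2×2 pixel footprint at fine grids, a single
    # pixel where one pixel already spans more than ~8 µm
    if max(grid.um_per_px_row, grid.um_per_px_col) <= 8.0:
        offsets = _STAMP_OFFSETS
    else:
        offsets = _STAMP_OFFSETS[:1]
    px_per_curve = 22 * len(offsets)
    for _ in range(150):
        count = int((cap & allowed).sum())
        deficit = target_px - count
        if deficit <= max(4, target_px // 500):
            break
        n_curves = max(1, deficit // px_per_curve)
        starts = allowed_idx[rng.integers(0, len(allowed_idx), size=n_curves)]
        for start in starts:
            path = _capillary_curve(rng, start.astype(float))
            pts = np.round(path).astype(int)[:, None, :] + offsets[None]
            pts = pts.reshape(-1, 2)
            ok = ((pts[:, 0] >= 0) & (pts[:, 0] < cap.shape[0])
                  & (pts[:, 1] >= 0) & (pts[:, 1] < cap.shape[1]))
            pts = pts[ok]
            keep = allowed[pts[:, 0], pts[:, 1]]
            cap[pts[keep, 0], pts[keep, 1]] = True
        _prune_thick_region(cap, grid, bbox)


def _trim_to_target(rng: np.random.Generator, cap: np.ndarray,
                    allowed: np.ndarray, target_px: int) -> None:
    """Add/remove individual pixels so the sector count is exact.

    Removals only thin existing structures; additions are kept 8-isolated
    from everything already drawn so they can never thicken a structure
    past the capillary caliber cap.
    """
    count = int((cap & allowed).sum())
    if count > target_px:
        idx = np.argwhere(cap & allowed)
        drop = idx[rng.permutation(len(idx))[:count - target_px]]
        cap[drop[:, 0], drop[:, 1]] = False
    elif count < target_px:
        need = target_px - count
        blocked = ndimage.binary_dilation(cap, structure=np.ones((3, 3), bool))
        cands = np.argwhere(allowed & ~blocked)
        cands = cands[rng.permutation(len(cands))]
        added = 0
        for r, c in cands:
            if added == need:
                break
            if not blocked[r, c]:
                cap[r, c] = True
                blocked[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2] = True
                added += 1
        # a residual shortfall in a very dense sector is tolerated: the
        # recorded ground-truth fraction is always an exact pixel count


def _artifact_mask(rng: np.random.Generator, config: SceneConfig) -> np.ndarray:
    grid = config.grid
    mask = np.zeros((grid.rows, grid.cols), dtype=bool)
    lo, hi = config.artifact_size_range_um
    rr = np.arange(grid.rows)[:, None] * grid.um_per_px_row
    cc = np.arange(grid.cols)[None, :] * grid.um_per_px_col
    for _ in range(config.artifact_patches):
        cy = rng.uniform(0, grid.rows) * grid.um_per_px_row
        cx = rng.uniform(0, grid.cols) * grid.um_per_px_col
        ay = rng.uniform(lo, hi) / 2.0
        ax = rng.uniform(lo, hi) / 2.0
        mask |= ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0
    return mask


def generate_angiogram(config: SceneConfig,
                       slab: Slab = Slab.SCP,
                       eye_id: str = "synthetic",
                       visit: str = "baseline"
                       ) -> tuple[EnFaceAngiogram, GroundTruth]:
    """Render one synthetic en-face angiogram plus its exact ground truth."""
    targets = config.sector_targets()
    grid = config.grid
    rng = np.random.default_rng(config.seed)

    disc = config.disc_ellipse()
    disc_mask = disc.interior_mask(grid)
    ring = build_ring_roi(disc, grid, width_um=config.ring_width_um)
    sectors = sectorize(ring, disc, grid)

    vessels = _draw_large_vessels(rng, config, disc)
    artifacts = _artifact_mask(rng, config)

    cap = np.zeros((grid.rows, grid.cols), dtype=bool)
    sector_allowed: dict[str, np.ndarray] = {}
    sector_target_px: dict[str, int] = {}
    measured_px: dict[str, int] = {}
    for sector in SECTOR_ORDER:
        allowed = sectors.mask(sector) & ring.mask & ~vessels & ~artifacts
        sector_allowed[sector.value] = allowed
        n = int(allowed.sum())
        measured_px[sector.value] = n
        sector_target_px[sector.value] = int(round(targets[sector.value] * n))
        if n and sector_target_px[sector.value]:
            _fill_sector_capillaries(rng, cap, allowed,
                                     sector_target_px[sector.value], grid)
    # one final global prune, then exact per-sector pixel adjustments that
    # cannot re-thicken anything (removals, or 8-isolated additions)
    cap[:] = _prune_thick(cap, grid)
    fractions: dict[str, float] = {}
    for sector in SECTOR_ORDER:
        allowed = sector_allowed[sector.value]
        n = measured_px[sector.value]
        if n and sector_target_px[sector.value]:
            _trim_to_target(rng, cap, allowed, sector_target_px[sector.value])
        fractions[sector.value] = (int((cap & allowed).sum()) / n
                                   if n else float("nan"))

    image = np.full((grid.rows, grid.cols), BACKGROUND_LEVEL, dtype=float)
    image[disc_mask] = DISC_LEVEL
    image[cap] = CAPILLARY_LEVEL
    image[vessels] = LARGE_VESSEL_LEVEL
    if config.speckle_shape is not None:
        k = float(config.speckle_shape)
        if k <= 0:
            raise SceneConfigError("speckle_shape must be positive or None")
        image *= rng.gamma(k, 1.0 / k, size=image.shape)
    image *= config.signal_strength / 10.0
    image[artifacts] = 0.0
    np.clip(image, 0.0, 1.0, out=image)

    angiogram = EnFaceAngiogram(pixels=image, grid=grid, slab=slab,
                                signal_strength=config.signal_strength,
                                eye_id=eye_id, visit=visit)
    truth = GroundTruth(perfusion_mask=cap | vessels, capillary_mask=cap,
                        vessel_mask=vessels, disc_mask=disc_mask,
                        artifact_mask=artifacts, ring=ring, sectors=sectors,
                        disc=disc, sector_fractions=fractions,
                        sector_measured_px=measured_px)
    return angiogram, truth


# ---------------------------------------------------------------------------
# longitudinal cohort generator
# ---------------------------------------------------------------------------

def _default_baseline_means() -> dict[str, dict[str, float]]:
    return {
        Slab.SCP.value: {"superior": 0.57, "temporal": 0.55,
                         "inferior": 0.58, "nasal": 0.54},
        Slab.DCP.value: {"superior": 0.53, "temporal": 0.52,
                         "inferior": 0.54, "nasal": 0.51},
    }


def _default_declines() -> dict[str, dict[str, tuple[float, float, float]]]:
    # post-operative decline offsets per visit (baseline, 6 mo, 12 mo):
    # superficial plexus — inferior falls first (6 mo), superior/temporal by
    # 12 mo, nasal stable; deep plexus — temporal and inferior fall from
    # 6 mo, superior by 12 mo, nasal stable.
    return {
        Slab.SCP.value: {"superior": (0.0, 0.0, -0.030),
                         "temporal": (0.0, 0.0, -0.035),
                         "inferior": (0.0, -0.030, -0.040),
                         "nasal": (0.0, 0.0, 0.0)},
        Slab.DCP.value: {"superior": (0.0, 0.0, -0.030),
                         "temporal": (0.0, -0.030, -0.040),
                         "inferior": (0.0, -0.030, -0.040),
                         "nasal": (0.0, 0.0, 0.0)},
    }


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the longitudinal cohort model (seed-deterministic)."""

    n_eyes: int = 33
    dr_fraction: float = 13.0 / 33.0
    visits: tuple[str, ...] = VISITS
    baseline_means: dict[str, dict[str, float]] = field(
        default_factory=_default_baseline_means)
    declines: dict[str, dict[str, tuple[float, ...]]] = field(
        default_factory=_default_declines)
    dr_dcp_deficit: float = -0.06   # additive DCP shift for DR eyes post-op
    sigma_between: float = 0.05     # eye-level random intercept SD
    sigma_noise: float = 0.02       # measurement noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 2:
            raise SceneConfigError("need at least 2 eyes")
        if not 0.0 <= self.dr_fraction <= 1.0:
            raise SceneConfigError("dr_fraction must be in [0,1]")
        if len(self.visits) < 2:
            raise SceneConfigError("need at least 2 visits")

    def null_effects(self) -> "CohortConfig":
        """Copy with all declines and the DR deficit zeroed (H0 cohort)."""
        zero = {slab: {sec: tuple(0.0 for _ in self.visits)
                       for sec in d} for slab, d in self.declines.items()}
        return replace(self, declines=zero, dr_dcp_deficit=0.0)


@dataclass(frozen=True)
class LongitudinalCohort:
    """Tidy per-eye/visit/slab/sector density table plus group labels."""

    data: pd.DataFrame  # columns: eye_id, group, visit, slab, sector, pvd
    visits: tuple[str, ...] = VISITS

    @property
    def n_eyes(self) -> int:
        return self.data["eye_id"].nunique()

    def group_counts(self) -> dict[str, int]:
        return (self.data.drop_duplicates("eye_id")["group"]
                .value_counts().to_dict())

    def panel(self, slab: Slab | str, sector: str) -> pd.DataFrame:
        """Subjects × visits matrix for one slab and sector ('mean' allowed)."""
        slab = Slab(slab).value
        df = self.data[self.data["slab"] == slab]
        if sector == "mean":
            df = (df.groupby(["eye_id", "visit"], as_index=False)["pvd"]
                  .mean())
        else:
            df = df[df["sector"] == Sector(sector).value]
        wide = df.pivot(index="eye_id", columns="visit", values="pvd")
        return wide[list(self.visits)]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.6f")

    @staticmethod
    def from_csv(path, visits: tuple[str, ...] | None = None
                 ) -> "LongitudinalCohort":
        df = pd.read_csv(path, dtype={"eye_id": str})
        required = {"eye_id", "group", "visit", "slab", "sector", "pvd"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort CSV lacks columns: {sorted(missing)}")
        if visits is None:
            seen = list(dict.fromkeys(df["visit"]))
            visits = tuple(v for v in VISITS if v in seen) or tuple(seen)
        return LongitudinalCohort(data=df, visits=visits)


def generate_cohort(config: CohortConfig) -> LongitudinalCohort:
    """Draw a balanced eye × visit × slab × sector density panel."""
    rng = np.random.default_rng(config.seed)
    n = config.n_eyes
    n_dr = int(round(config.dr_fraction * n))
    groups = np.array(["DR"] * n_dr + ["no-DR"] * (n - n_dr))
    rng.shuffle(groups)
    intercepts = rng.normal(0.0, config.sigma_between, size=n)

    rows = []
    for i in range(n):
        eye = f"E{i + 1:02d}"
        for slab in (Slab.SCP, Slab.DCP):
            means = config.baseline_means[slab.value]
            declines = config.declines[slab.value]
            for t, visit in enumerate(config.visits):
                dr_shift = (config.dr_dcp_deficit
                            if (groups[i] == "DR" and slab is Slab.DCP
                                and t > 0) else 0.0)
                for sector in SECTOR_ORDER:
                    mu = (means[sector.value] + declines[sector.value][t]
                          + dr_shift + intercepts[i]
                          + rng.normal(0.0, config.sigma_noise))
                    rows.append((eye, groups[i], visit, slab.value,
                                 sector.value, float(np.clip(mu, 0.0, 1.0))))
    df = pd.DataFrame(rows, columns=["eye_id", "group", "visit", "slab",
                                     "sector", "pvd"])
    return LongitudinalCohort(data=df, visits=tuple(config.visits))
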