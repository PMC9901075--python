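"""File I/O and run configuration.

Angiograms are read from ordinary single-channel 8/16-bit rasters (PNG or
TIFF) and min-max normalized to [0, 1] per image — every threshold in the
pipeline is mean-relative, so only relative intensities matter.  Masks are
0/255 single-channel PNGs aligned to the angiogram raster; density reports
are CSVs with a stable column order, fractions at 6 decimals and the
configuration hash that produced them, so re-running the same configuration
on the same inputs yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .geometry import DiscEllipse, Laterality, ScanGrid, fit_disc_ellipse
from .perfusion import (DEFAULT_KERNEL_SIDE, EnFaceAngiogram, QuantifyResult,
                        Slab, ThresholdPolicy)


class FormatError(ValueError):
    pass


class MetadataError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline, hashable for provenance stamping."""

    roi_width_um: float = 750.0
    kernel_side: int = DEFAULT_KERNEL_SIDE
    threshold_policy: str = ThresholdPolicy.MEAN_GLOBAL.value
    adjustment_factor: float = 1.0
    min_caliber_um: float = 30.0
    vessel_dilation_um: float = 10.0
    min_npa_area_um2: float = 0.0
    scan_width_mm: float = 6.0
    scan_height_mm: float = 6.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True) + "\n")

    @staticmethod
    def load(path) -> "RunConfig":
        return RunConfig(**json.loads(Path(path).read_text()))


def _load_gray(path) -> np.ndarray:
    try:
        img = Image.open(path)
    except OSError as exc:
        raise FormatError(f"cannot read raster {path}: {exc}") from exc
    if img.mode in ("RGB", "RGBA", "P", "CMYK"):
        raise FormatError(
            f"{path}: multi-channel image; a single-channel grayscale "
            "raster is required")
    return np.asarray(img, dtype=float)


def read_angiogram(path, slab: Slab | str, laterality: Laterality | str = "OD",
                   scan_width_mm: float = 6.0,
                   scan_height_mm: float | None = None,
                   signal_strength: int = 10,
                   eye_id: str = "", visit: str = "") -> EnFaceAngiogram:
    """Load one en-face slab image and normalize intensities to [0, 1].

    A scan with signal strength below 7/10 is loaded but flagged; the
    quantification stage refuses it unless forced.
    """
    if scan_width_mm is None or scan_width_mm <= 0:
        raise MetadataError("scan_width_mm must be a positive length")
    if scan_height_mm is None:
        scan_height_mm = scan_width_mm
    pixels = _load_gray(path)
    if pixels.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D raster")
    lo, hi = pixels.min(), pixels.max()
    pixels = (pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(pixels)
    grid = ScanGrid(rows=pixels.shape[0], cols=pixels.shape[1],
                    scan_width_mm=scan_width_mm, scan_height_mm=scan_height_mm,
                    laterality=Laterality(laterality))
    return EnFaceAngiogram(pixels=pixels, grid=grid, slab=Slab(slab),
                           signal_strength=int(signal_strength),
                           eye_id=eye_id, visit=visit)


def write_image(path, pixels: np.ndarray, bit_depth: int = 16) -> None:
    """Write a [0,1] float raster as an 8- or 16-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    if bit_depth == 8:
        Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)
    elif bit_depth == 16:
        data = (arr * 65535).round().astype("<u2")
        Image.fromarray(data).save(path)  # 16-bit grayscale (I;16)
    else:
        raise FormatError("bit_depth must be 8 or 16")


def write_mask(path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8),
                    mode="L").save(path)


def read_mask(path) -> np.ndarray:
    return _load_gray(path) > 0


def read_disc_spec(path, grid: ScanGrid) -> DiscEllipse:
    """Disc boundary from a JSON ellipse record, a point list, or a mask PNG.

    JSON fields: center_row, center_col, a_um, b_um, rotation_deg.  A plain
    text file holds one ``row col`` pair per line.  Any other extension is
    treated as a binary mask image.
    """
    p = Path(path)
    if p.suffix.lower() == ".json":
        rec = json.loads(p.read_text())
        try:
            return DiscEllipse(center_row=float(rec["center_row"]),
                               center_col=float(rec["center_col"]),
                               semi_axis_a_um=float(rec["a_um"]),
                               semi_axis_b_um=float(rec["b_um"]),
                               rotation=np.deg2rad(float(rec.get("rotation_deg", 0.0))))
        except KeyError as exc:
            raise MetadataError(f"disc JSON missing field {exc}") from exc
    if p.suffix.lower() in (".txt", ".csv", ".pts"):
        pts = np.loadtxt(p, ndmin=2)
        return fit_disc_ellipse(boundary_points=pts, grid=grid)
    return fit_disc_ellipse(disc_mask=read_mask(p), grid=grid)


REPORT_COLUMNS = ("eye_id", "visit", "slab", "pvd_superior", "pvd_temporal",
                  "pvd_inferior", "pvd_nasal", "pvd_mean", "npa_fraction",
                  "threshold_used", "excluded_px_vessels",
                  "excluded_px_artifacts", "excluded_px_disc",
                  "config_hash", "tool_version")


def write_density_report(results, path, config: RunConfig | None = None) -> None:
    """Serialize quantification results as a stable, diffable CSV.

    ``results`` may hold :class:`QuantifyResult` objects (full pipeline
    output) or bare :class:`QuadrantDensityRecord` objects (NPA and
    exclusion columns left empty).
    """
    config = config or RunConfig()
    rows = []
    for res in results:
        if isinstance(res, QuantifyResult):
            rec, npa = res.record, res.npa
            excl = res.measured.excluded_px
            threshold = res.threshold_used
        else:
            rec, npa, excl, threshold = res, None, {}, float("nan")
        rows.append({
            "eye_id": rec.eye_id, "visit": rec.visit, "slab": Slab(rec.slab).value,
            "pvd_superior": rec.pvd_superior, "pvd_temporal": rec.pvd_temporal,
            "pvd_inferior": rec.pvd_inferior, "pvd_nasal": rec.pvd_nasal,
            "pvd_mean": rec.pvd_mean,
            "npa_fraction": npa.npa_fraction if npa else float("nan"),
            "threshold_used": threshold,
            "excluded_px_vessels": excl.get("vessels", 0),
            "excluded_px_artifacts": excl.get("artifacts", 0),
            "excluded_px_disc": excl.get("disc", 0),
            "config_hash": config.config_hash(),
            "tool_version": __version__,
        })
    df = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    df.to_csv(path, index=False, float_format="%.6f")


def read_density_report(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"eye_id": str, "visit": str})
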