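"""Evaluation diagnostics: low-temperature zones, mean temperature,
contour rendering, PSNR and SSIM map comparison.

A low-temperature zone is a connected region of the cross-section colder
than a threshold (15 degC by convention).  Zones are segmented as
4-connected components of the sub-threshold mask; their areas are
measured with sub-cell accuracy by integrating the threshold contour
(marching squares) and clipping it to the physical domain, so that
area discrepancies well below one grid cell remain meaningful.

Field maps are compared as images the way monitored and simulated
contour maps are compared: fields are rendered deterministically to
8-bit grayscale through a fixed level-band pipeline, then scored with
PSNR (10 log10(peak^2 / MSE), infinite for identical images) and SSIM
(mean local structural similarity, Gaussian 11x11 window, sigma 1.5,
stabilizers K1=0.01, K2=0.03).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon, box
from shapely.ops import unary_union
from skimage import measure
from skimage.metrics import structural_similarity

from .field_reconstruction import PlanarGrid

__all__ = ["Zone", "ZoneReport", "MapComparison", "mean_temperature",
           "detect_low_temp_zones", "area_discrepancy", "psnr", "ssim",
           "compare_maps", "render_contour", "contour_polylines"]

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass(frozen=True)
class Zone:
    label: int
    area: float                   # m^2
    centroid: tuple[float, float]  # (horizontal, height), m


@dataclass(frozen=True)
class ZoneReport:
    """Segmented low-temperature zones of one plane at one time."""

    threshold: float              # degC
    zones: tuple[Zone, ...]       # sorted by area, descending
    date: str | None = None
    plane: str | None = None

    @property
    def count(self) -> int:
        return len(self.zones)

    @property
    def total_area(self) -> float:
        return float(sum(z.area for z in self.zones))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"date": self.date, "plane": self.plane, "zone": z.label,
              "area_m2": z.area, "centroid_h": z.centroid[0],
              "centroid_z": z.centroid[1]} for z in self.zones])

    def to_json(self, path=None):
        payload = {"date": self.date, "plane": self.plane,
                   "threshold_C": self.threshold,
                   "total_area_m2": self.total_area,
                   "zones": [{"label": z.label, "area_m2": z.area,
                              "centroid": list(z.centroid)} for z in self.zones]}
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass(frozen=True)
class MapComparison:
    """PSNR/SSIM/MSE scores between two rendered field maps."""

    mse: float
    psnr_db: float                # inf when mse == 0
    ssim: float

    def __post_init__(self) -> None:
        if (self.mse == 0.0) != math.isinf(self.psnr_db):
            raise ValueError("psnr is infinite exactly when mse is zero")


def mean_temperature(grid: PlanarGrid | np.ndarray) -> float:
    """Area-weighted plane-mean temperature (uniform cells: plain mean)."""
    values = grid.values if isinstance(grid, PlanarGrid) else np.asarray(grid)
    return float(np.mean(values))


def _contour_polygons(values: np.ndarray, threshold: float,
                      a1: np.ndarray, a2: np.ndarray):
    """Closed sub-threshold polygons in physical coordinates.

    The grid is padded with a supra-threshold rim so that regions touching
    the boundary close; polygons are clipped back to the physical domain
    (cell-centered grid: half a spacing beyond the outer nodes).
    """
    dx1 = a1[1] - a1[0] if len(a1) > 1 else 1.0
    dx2 = a2[1] - a2[0] if len(a2) > 1 else dx1
    pad_value = threshold + max(10.0, abs(threshold))
    padded = np.pad(values, 1, constant_values=pad_value)
    contours = measure.find_contours(padded, threshold)
    domain = box(a1[0] - dx1 / 2, a2[0] - dx2 / 2,
                 a1[-1] + dx1 / 2, a2[-1] + dx2 / 2)
    polys = []
    for c in contours:
        if len(c) < 3:
            continue
        # padded index -> physical: row r maps to a2[0] + (r-1)*dx2
        ph = np.column_stack([a1[0] + (c[:, 1] - 1) * dx1,
                              a2[0] + (c[:, 0] - 1) * dx2])
        poly = Polygon(ph)
        if not poly.is_valid:
            poly = poly.buffer(0)
        poly = poly.intersection(domain)
        if not poly.is_empty:
            polys.append(poly)
    return polys


def detect_low_temp_zones(grid: PlanarGrid, threshold: float = 15.0,
                          min_zone_area: float = 0.05,
                          date: str | None = None,
                          plane: str | None = None) -> ZoneReport:
    """Segment sub-threshold regions into 4-connected zones with sub-cell
    areas.

    Components smaller than ``min_zone_area`` (m^2) are discarded as
    single-node noise.  Zones are reported sorted by area, largest first.
    """
    values = grid.values
    if not np.all(np.isfinite(values)):
        raise ValueError("grid contains non-finite values")
    mask = values < threshold
    if not mask.any():
        return ZoneReport(threshold=threshold, zones=(), date=date, plane=plane)
    labels, n_labels = ndimage.label(mask, structure=FOUR_CONNECTED)
    polys = _contour_polygons(values, threshold, grid.axis1_coords,
                              grid.axis2_coords)
    dx1 = grid.axis1_coords[1] - grid.axis1_coords[0] \
        if len(grid.axis1_coords) > 1 else grid.spacing
    dx2 = grid.axis2_coords[1] - grid.axis2_coords[0] \
        if len(grid.axis2_coords) > 1 else dx1

    def label_at(pt) -> int:
        i = int(round((pt.x - grid.axis1_coords[0]) / dx1))
        k = int(round((pt.y - grid.axis2_coords[0]) / dx2))
        i = min(max(i, 0), labels.shape[1] - 1)
        k = min(max(k, 0), labels.shape[0] - 1)
        return int(labels[k, i])

    outers: dict[int, list] = {}
    holes: list = []
    for poly in polys:
        parts = poly.geoms if hasattr(poly, "geoms") else [poly]
        for part in parts:
            if part.is_empty or part.area == 0:
                continue
            pt = part.representative_point()
            lab = label_at(pt)
            if lab > 0:
                outers.setdefault(lab, []).append(part)
            else:
                holes.append(part)

    hole_union = unary_union(holes) if holes else None
    zones = []
    X, Z = grid.mesh()
    for lab in range(1, n_labels + 1):
        if lab in outers:
            geom = unary_union(outers[lab])
            if hole_union is not None:
                geom = geom.difference(hole_union)
            area = float(geom.area)
        else:
            # component with no resolvable contour (e.g. whole grid cold
            # or a single node); fall back to cell counting
            area = float(np.sum(labels == lab)) * dx1 * dx2
        if area < min_zone_area:
            continue
        sel = labels == lab
        centroid = (float(X[sel].mean()), float(Z[sel].mean()))
        zones.append(Zone(label=lab, area=area, centroid=centroid))
    zones.sort(key=lambda z: -z.area)
    zones = tuple(Zone(label=i + 1, area=z.area, centroid=z.centroid)
                  for i, z in enumerate(zones))
    return ZoneReport(threshold=threshold, zones=zones, date=date, plane=plane)


def area_discrepancy(monitored: float, simulated: float) -> tuple[float, float]:
    """Absolute (m^2) and relative (%) discrepancy between a monitored and
    a simulated zone area, both rounded to 2 decimals."""
    if monitored <= 0:
        raise ValueError("monitored area must be positive")
    absolute = abs(monitored - simulated)
    relative = 100.0 * absolute / monitored
    return round(absolute, 2), round(relative, 2)


def psnr(a: np.ndarray, b: np.ndarray, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(peak^2 / MSE).

    Infinite for identical images.  ``peak`` defaults to 255 for uint8
    inputs and to the joint value range otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shape mismatch: {a.shape} vs {b.shape}")
    if peak is None:
        peak = 255.0 if np.asarray(a).dtype == np.uint8 else \
            float(max(a.max(), b.max()) - min(a.min(), b.min())) or 1.0
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """Mean structural similarity index.

    Gaussian weighting window (sigma = 1.5, 11x11 support), stabilizers
    K1 = 0.01 and K2 = 0.03, dynamic range from the image dtype for
    integer images.  Symmetric; equals 1 exactly on identical inputs.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"image shape mismatch: {a.shape} vs {b.shape}")
    if data_range is None:
        if np.issubdtype(a.dtype, np.integer):
            info = np.iinfo(a.dtype)
            data_range = float(info.max - info.min)
        else:
            data_range = float(max(a.max(), b.max()) - min(a.min(), b.min())) or 1.0
    return float(structural_similarity(
        a.astype(float), b.astype(float), data_range=data_range,
        gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
        K1=0.01, K2=0.03))


def compare_maps(a: np.ndarray, b: np.ndarray,
                 peak: float | None = None) -> MapComparison:
    """Bundle MSE, PSNR and SSIM of two rendered maps."""
    a_f = np.asarray(a, dtype=float)
    b_f = np.asarray(b, dtype=float)
    if a_f.shape != b_f.shape:
        raise ValueError(f"image shape mismatch: {a_f.shape} vs {b_f.shape}")
    mse = float(np.mean((a_f - b_f) ** 2))
    return MapComparison(mse=mse, psnr_db=psnr(a, b, peak), ssim=ssim(a, b))


DEFAULT_LEVELS = tuple(np.arange(10.0, 36.0, 1.0))


def render_contour(grid: PlanarGrid, levels=DEFAULT_LEVELS) -> np.ndarray:
    """Render a field to a deterministic 8-bit grayscale contour-band map.

    Values are quantized into the fixed level bands and the band index is
    spread linearly over 0..255 -- the image analogue of a filled contour
    plot with a fixed colormap and level set.  Identical grids render to
    identical bytes.
    """
    values = grid.values
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot render non-finite values")
    levels = np.asarray(sorted(levels), dtype=float)
    bands = np.digitize(values, levels)           # 0 .. len(levels)
    img = np.round(bands * (255.0 / max(len(levels), 1))).astype(np.uint8)
    return img


def contour_polylines(grid: PlanarGrid, level: float) -> list[np.ndarray]:
    """Vector contours of one level as (n, 2) polylines in plane
    coordinates (horizontal, height)."""
    cs = measure.find_contours(grid.values, level)
    dx1 = grid.axis1_coords[1] - grid.axis1_coords[0]
    dx2 = grid.axis2_coords[1] - grid.axis2_coords[0]
    out = []
    for c in cs:
        out.append(np.column_stack([grid.axis1_coords[0] + c[:, 1] * dx1,
                                    grid.axis2_coords[0] + c[:, 0] * dx2]))
    return out


def save_contour_png(grid: PlanarGrid, path, levels=DEFAULT_LEVELS,
                     cmap: str = "coolwarm") -> None:
    """Filled-contour PNG export (presentation only; metric comparisons
    use :func:`render_contour`)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(8, 3))
    X, Z = grid.mesh()
    cf = ax.contourf(X, Z, grid.values, levels=list(levels), cmap=cmap,
                     extend="both")
    fig.colorbar(cf, ax=ax, label="temperature (degC)")
    ax.set_xlabel(f"{grid.axes[0]} (m)")
    ax.set_ylabel(f"{grid.axes[1]} (m)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
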