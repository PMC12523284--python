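"""Continuous planar temperature fields from discrete sensors.

Scattered sensor temperatures are interpolated with a cubic radial basis
function, phi(r) = r^3, augmented with a degree-1 polynomial tail and the
usual orthogonality side conditions -- the standard well-posed form of
cubic RBF interpolation.  The fit is exact (no smoothing): the model
reproduces every input value at its own position.

Plane reconstruction extracts the sensors lying within a slab around the
requested cross-section, projects them onto it, fits the RBF and
evaluates it on a uniform grid ready for contouring and diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator
from scipy.spatial.distance import pdist

from .sensor_data import SensorCampaign

logger = logging.getLogger(__name__)

__all__ = ["RbfModel", "PlanarGrid", "fit_rbf", "evaluate_field",
           "reconstruct_plane", "ExtrapolationError", "ReconstructionError"]


class ExtrapolationError(ValueError):
    """Grid nodes requested far outside the data support."""


class ReconstructionError(ValueError):
    """Too few usable sensors for a plane reconstruction."""


@dataclass(frozen=True)
class PlanarGrid:
    """A uniform 2-D grid of values on a vertical cross-section.

    ``values[k, i]`` corresponds to ``(axis1_coords[i], axis2_coords[k])``
    -- horizontal coordinate first, height second.
    """

    axes: tuple[str, str]            # e.g. ("x", "z") or ("y", "z")
    axis1_coords: np.ndarray         # horizontal axis, m
    axis2_coords: np.ndarray         # vertical axis (height), m
    values: np.ndarray               # shape (len(axis2), len(axis1))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a1 = np.asarray(self.axis1_coords, dtype=float)
        a2 = np.asarray(self.axis2_coords, dtype=float)
        v = np.asarray(self.values, dtype=float)
        for a in (a1, a2):
            if len(a) > 1:
                d = np.diff(a)
                if np.any(d <= 0) or not np.allclose(d, d[0]):
                    raise ValueError("grid coordinates must be uniform and increasing")
        if v.shape != (len(a2), len(a1)):
            raise ValueError(f"values shape {v.shape} does not match "
                             f"coordinates ({len(a2)}, {len(a1)})")
        object.__setattr__(self, "axis1_coords", a1)
        object.__setattr__(self, "axis2_coords", a2)
        object.__setattr__(self, "values", v)

    @property
    def spacing(self) -> float:
        return float(self.axis1_coords[1] - self.axis1_coords[0]) \
            if len(self.axis1_coords) > 1 \
            else float(self.axis2_coords[1] - self.axis2_coords[0])

    @property
    def cell_area(self) -> float:
        return self.spacing ** 2

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.axis1_coords, self.axis2_coords)

    def to_csv(self, path) -> None:
        """Matrix CSV: first column the height coordinate, header the
        horizontal coordinate."""
        df = pd.DataFrame(self.values, index=self.axis2_coords,
                          columns=self.axis1_coords)
        df.index.name = self.axes[1]
        df.to_csv(path)

    def to_dataset(self):
        """Self-describing xarray representation."""
        import xarray as xr
        return xr.DataArray(
            self.values,
            coords={self.axes[1]: self.axis2_coords,
                    self.axes[0]: self.axis1_coords},
            dims=(self.axes[1], self.axes[0]),
            attrs=dict(self.meta),
        ).to_dataset(name="value")


@dataclass(frozen=True)
class RbfModel:
    """A fitted cubic RBF interpolant over scattered 2-D points."""

    centers: np.ndarray              # (n, 2) sensor positions, m
    values: np.ndarray               # (n,) fitted temperatures
    kernel: str                      # "cubic"
    _interp: RBFInterpolator = field(repr=False, compare=False, default=None)

    @property
    def weights(self) -> np.ndarray:
        """RBF coefficients, one per center."""
        return np.asarray(self._interp._coeffs)[: len(self.centers), 0]

    @property
    def polynomial_tail(self) -> np.ndarray:
        """Degree-1 tail coefficients (1, x, z)."""
        return np.asarray(self._interp._coeffs)[len(self.centers):, 0]

    def __call__(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self._interp(pts)


def fit_rbf(points, values, kernel: str = "cubic") -> RbfModel:
    """Interpolate scattered values with a cubic RBF and linear tail.

    Requires at least 3 non-collinear points; duplicate positions are
    rejected (conflicting duplicates are a data error, exact duplicates
    make the system singular).  The returned model reproduces every input
    value at its own center to interpolation accuracy (<1e-6).
    """
    pts = np.asarray(points, dtype=float)
    vals = np.asarray(values, dtype=float).ravel()
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if len(pts) != len(vals):
        raise ValueError("points and values length mismatch")
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a 2-D fit")
    # duplicate / near-duplicate detection with a helpful message
    from scipy.spatial import cKDTree
    tree = cKDTree(pts)
    pairs = tree.query_pairs(1e-9)
    if pairs:
        i, j = sorted(pairs)[0]
        if abs(vals[i] - vals[j]) > 1e-12:
            raise ValueError(
                f"duplicate positions with conflicting values: points {i} and "
                f"{j} at {pts[i]} carry {vals[i]} vs {vals[j]}")
        raise ValueError(f"near-duplicate points {i} and {j} at {pts[i]} "
                         "make the interpolation system singular")
    # collinearity check (degree-1 tail needs a non-degenerate point set)
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError("points are collinear; 2-D RBF fit is ill-posed")
    interp = RBFInterpolator(pts, vals, kernel=kernel, degree=1,
                             smoothing=0.0)
    model = RbfModel(centers=pts, values=vals, kernel=kernel, _interp=interp)
    resid = np.max(np.abs(model(pts).ravel() - vals))
    if resid > 1e-6:
        raise ValueError(f"interpolation residual {resid:.3g} exceeds 1e-6; "
                         "the system is near-singular")
    return model


def evaluate_field(model: RbfModel, axis1_coords, axis2_coords,
                   extrapolation_margin: float = 2.0,
                   strict: bool = False,
                   axes: tuple[str, str] = ("x", "z")) -> PlanarGrid:
    """Evaluate a fitted model on a uniform planar grid.

    Nodes beyond the bounding box of the data support plus
    ``extrapolation_margin`` (m) trigger a warning, escalated to
    :class:`ExtrapolationError` when ``strict``.
    """
    a1 = np.asarray(axis1_coords, dtype=float)
    a2 = np.asarray(axis2_coords, dtype=float)
    lo, hi = model.centers.min(axis=0), model.centers.max(axis=0)
    out_of_support = (a1.min() < lo[0] - extrapolation_margin
                      or a1.max() > hi[0] + extrapolation_margin
                      or a2.min() < lo[1] - extrapolation_margin
                      or a2.max() > hi[1] + extrapolation_margin)
    if out_of_support:
        msg = ("grid extends more than %.2f m beyond the sensor support "
               "box [%s, %s]" % (extrapolation_margin, lo, hi))
        if strict:
            raise ExtrapolationError(msg)
        logger.warning(msg)
    X, Z = np.meshgrid(a1, a2)
    vals = model(np.column_stack([X.ravel(), Z.ravel()])).reshape(X.shape)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values in RBF evaluation")
    return PlanarGrid(axes=axes, axis1_coords=a1, axis2_coords=a2, values=vals)


def reconstruct_plane(campaign: SensorCampaign, date, plane: str = "XOZ",
                      offset: float | None = None,
                      slab_halfwidth: float = 1.0,
                      spacing: float = 0.1,
                      extent: tuple[float, float] | None = None,
                      height: float | None = None) -> PlanarGrid:
    """Reconstruct a vertical cross-section from one day of sensor data.

    ``plane`` is ``"XOZ"`` (section at constant y = ``offset``) or
    ``"YOZ"`` (constant x).  Sensors within ``slab_halfwidth`` of the
    plane are projected onto it; at least 3 are required.
    """
    plane = plane.upper()
    if plane not in ("XOZ", "YOZ"):
        raise ValueError("plane must be XOZ or YOZ")
    layout = campaign.layout
    if offset is None:
        offset = (layout.plan_y if plane == "XOZ" else layout.plan_x) / 2.0
    readings = campaign.on_date(date)
    if not readings:
        raise ReconstructionError(f"no readings on {date}")
    horiz = (lambda p: p[0]) if plane == "XOZ" else (lambda p: p[1])
    perp = (lambda p: p[1]) if plane == "XOZ" else (lambda p: p[0])
    near = [r for r in readings if abs(perp(r.position) - offset) <= slab_halfwidth]
    if len(near) < 3:
        raise ReconstructionError(
            f"only {len(near)} sensors within {slab_halfwidth} m of the "
            f"{plane} plane at offset {offset} m; need at least 3")
    pts = np.array([[horiz(r.position), r.position[2]] for r in near])
    vals = np.array([r.temperature for r in near])
    model = fit_rbf(pts, vals)
    h_extent = extent or (0.0, layout.plan_x if plane == "XOZ" else layout.plan_y)
    v_extent = (0.0, height if height is not None else layout.fill_height)
    a1 = np.arange(h_extent[0] + spacing / 2, h_extent[1], spacing)
    a2 = np.arange(v_extent[0] + spacing / 2, v_extent[1], spacing)
    axes = ("x", "z") if plane == "XOZ" else ("y", "z")
    grid = evaluate_field(model, a1, a2, axes=axes)
    grid.meta.update(plane=plane, offset=offset, date=str(pd.Timestamp(date).date()),
                     sensors=[r.sensor_id for r in near])
    return grid
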