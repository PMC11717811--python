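"""Geometry of the explant and time-lapse migration assays.

Conventions: X is the lateral axis (parallel to the white matter), Y is the
radial axis (toward the cortex); images are assumed oriented cortex-up, and
the cortex side of the white-matter curve is +Y unless flipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from shapely.geometry import LineString, Point
from skimage.measure import label as cc_label, regionprops

from .coloc import binarize_channel
from .errors import ParameterError

logger = logging.getLogger(__name__)


def net_distance(p1, p2) -> float:
    """Euclidean distance between two points (µm)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return float(np.hypot(p2[0] - p1[0], p2[1] - p1[1]))


def axis_distance(p1, p2, axis: str) -> float:
    """Absolute displacement along one named axis (µm).

    axis='lateral_x' takes |x2 - x1|; axis='radial_y' takes |y2 - y1|.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if axis in ("lateral_x", "lateral", "x"):
        return float(abs(p2[0] - p1[0]))
    if axis in ("radial_y", "radial", "y"):
        return float(abs(p2[1] - p1[1]))
    raise ParameterError(f"axis must be 'lateral_x' or 'radial_y', got {axis!r}")


def migration_speed(d_um: float, t_h: float) -> float:
    """Speed v = d / t in µm/h."""
    if not t_h > 0:
        raise ParameterError(f"duration must be positive, got {t_h}")
    return float(d_um) / float(t_h)


REQUIRED_RECORD_COLUMNS = ("cell_id", "litter", "slice", "treatment", "x1", "y1", "x2", "y2")


def derive_records(points: pd.DataFrame) -> pd.DataFrame:
    """Add net/lateral/radial displacements (and speed when t_h > 0) to a point table.

    Expects columns cell_id, litter, slice, treatment, x1, y1, x2, y2 and
    optionally t_h (hours) and cc_to_ctx (µm). Guarantees
    net**2 == lateral**2 + radial**2 to machine precision.
    """
    missing = [c for c in REQUIRED_RECORD_COLUMNS if c not in points.columns]
    if missing:
        raise ParameterError(f"point table lacks columns: {missing}")
    out = points.copy()
    dx = out["x2"].to_numpy(float) - out["x1"].to_numpy(float)
    dy = out["y2"].to_numpy(float) - out["y1"].to_numpy(float)
    out["lateral"] = np.abs(dx)
    out["radial"] = np.abs(dy)
    out["net"] = np.hypot(dx, dy)
    if "t_h" in out.columns:
        t = out["t_h"].to_numpy(float)
        if np.any(t <= 0):
            raise ParameterError("t_h must be positive wherever supplied")
        out["v_um_h"] = out["net"] / t
    return out


def speeds_from_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-cell speed from the first and last frame of each track.

    v = net displacement between the endpoints divided by elapsed time.
    """
    for col in ("cell_id", "t_h", "x_um", "y_um"):
        if col not in tracks.columns:
            raise ParameterError(f"track table lacks column {col!r}")
    rows = []
    for cell_id, g in tracks.sort_values(["cell_id", "t_h"]).groupby("cell_id", sort=False):
        if len(g) < 2:
            raise ParameterError(f"track {cell_id!r} has fewer than 2 frames")
        first, last = g.iloc[0], g.iloc[-1]
        d = net_distance((first.x_um, first.y_um), (last.x_um, last.y_um))
        dt = float(last.t_h - first.t_h)
        rows.append({"cell_id": cell_id, "d_um": d, "t_h": dt, "v_um_h": migration_speed(d, dt)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# white-matter curve
# ---------------------------------------------------------------------------

@dataclass
class CurveModel:
    """Smoothed planar curve through operator-marked points, with a side convention.

    ``samples`` is a dense polyline (N x 2, µm); distance queries measure the
    minimum distance to its segments. ``cortex_positive_y`` fixes which side
    counts as cortex.
    """

    control_points: np.ndarray
    smoothing: float
    samples: np.ndarray
    cortex_positive_y: bool = True

    def y_at(self, x: float) -> float:
        """Curve height at x (clamped to the sampled range)."""
        xs = self.samples[:, 0]
        return float(np.interp(x, xs, self.samples[:, 1]))

    @property
    def _linestring(self) -> LineString:
        if not hasattr(self, "_ls_cache"):
            self._ls_cache = LineString(self.samples)
        return self._ls_cache


def smooth_white_matter_curve(
    points,
    smoothing: float = 0.0,
    sample_spacing_um: float = 0.25,
    cortex_positive_y: bool = True,
) -> CurveModel:
    """Fit a smoothing spline through operator-marked white-matter points.

    Points are sorted by x; duplicate x values are de-duplicated (mean y)
    with a warning. smoothing=0 interpolates the points exactly. Two points
    give a straight segment. The curve is sampled at <= `sample_spacing_um`
    spacing in x.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ParameterError("need >= 2 (x, y) control points")
    order = np.argsort(pts[:, 0], kind="stable")
    pts = pts[order]
    if np.any(np.diff(pts[:, 0]) == 0):
        logger.warning("duplicate x in control points; averaging duplicates")
        df = pd.DataFrame(pts, columns=["x", "y"]).groupby("x", as_index=False).mean()
        pts = df.to_numpy()
        if pts.shape[0] < 2:
            raise ParameterError("fewer than 2 distinct x values in control points")

    x, y = pts[:, 0], pts[:, 1]
    n_samples = max(int(np.ceil((x[-1] - x[0]) / sample_spacing_um)) + 1, 2)
    xs = np.linspace(x[0], x[-1], n_samples)
    if len(x) == 2:
        ys = np.interp(xs, x, y)
    else:
        k = min(3, len(x) - 1)
        spline = UnivariateSpline(x, y, k=k, s=float(smoothing))
        ys = spline(xs)
    return CurveModel(pts, float(smoothing), np.column_stack([xs, ys]), cortex_positive_y)


def distance_to_curve(cell, curve: CurveModel) -> float:
    """Signed shortest distance from a point to the curve (µm).

    Magnitude is the minimum distance to the sampled polyline's segments;
    the sign is positive on the cortex side (above the curve when
    ``cortex_positive_y``), negative otherwise. Only positive values count
    as CC-to-CTX migration.
    """
    cell = np.asarray(cell, dtype=float)
    d = float(curve._linestring.distance(Point(cell[0], cell[1])))
    above = cell[1] > curve.y_at(cell[0])
    sign = 1.0 if (above == curve.cortex_positive_y) else -1.0
    return sign * d


def cc_to_ctx_distances(points: pd.DataFrame, curve: CurveModel) -> pd.DataFrame:
    """Signed curve distance for each endpoint; cortex-side flag included."""
    out = points.copy()
    d = [distance_to_curve((row.x2, row.y2), curve) for row in out.itertuples()]
    out["cc_to_ctx_signed"] = d
    out["in_cortex"] = out["cc_to_ctx_signed"] > 0
    out["cc_to_ctx"] = np.where(out["in_cortex"], out["cc_to_ctx_signed"], np.nan)
    return out


# ---------------------------------------------------------------------------
# migrated-cell counting
# ---------------------------------------------------------------------------

def count_migrated(
    reporter_image: np.ndarray,
    implant_center_um: tuple[float, float],
    implant_radius_um: float = 500.0,
    cortex_mask: np.ndarray | None = None,
    min_area_px: int = 20,
    pixel_size_um: float = 1.0,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
) -> dict:
    """Count reporter-positive cells outside the implant site.

    Binarizes the reporter channel, labels 8-connected components, drops
    components smaller than ``min_area_px``, excludes components whose
    centroid falls inside the implant ROI (center + radius, µm), and
    reports the outside-implant count plus the count whose centroid lies in
    the cortex mask.
    """
    image = np.asarray(reporter_image, dtype=float)
    if cortex_mask is not None:
        cortex_mask = np.asarray(cortex_mask, dtype=bool)
        if cortex_mask.shape != image.shape:
            raise ParameterError("cortex mask shape differs from the image")
    if implant_radius_um < 0:
        raise ParameterError("implant radius must be >= 0")
    if implant_radius_um == 0:
        logger.warning("zero-radius implant ROI: no components will be excluded")

    binary = binarize_channel(image, threshold_method, fixed_threshold)
    labeled = cc_label(binary, connectivity=2)
    cx_um, cy_um = float(implant_center_um[0]), float(implant_center_um[1])

    n_outside = n_cortex = n_implant = n_small = 0
    for prop in regionprops(labeled):
        if prop.area < min_area_px:
            n_small += 1
            continue
        row, col = prop.centroid
        x_um, y_um = col * pixel_size_um, row * pixel_size_um
        if np.hypot(x_um - cx_um, y_um - cy_um) <= implant_radius_um and implant_radius_um > 0:
            n_implant += 1
            continue
        n_outside += 1
        if cortex_mask is not None and cortex_mask[int(round(row)), int(round(col))]:
            n_cortex += 1
    return {
        "n_outside": n_outside,
        "n_cortex": n_cortex,
        "n_in_implant": n_implant,
        "n_below_min_area": n_small,
        "min_area_px": min_area_px,
        "implant_radius_um": implant_radius_um,
    }
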