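"""Per-cell marker-positivity scoring from a reporter label mask and a marker channel.

The scoring procedure mirrors a common confocal colocalization workflow:
segmented cells arrive as an integer label mask, the marker channel is
binarized, a per-cell region (whole cell, membrane ring, or nucleus) is
intersected with the binarized marker, and a cell is called positive when
the overlap fraction strictly exceeds a threshold (default 0.6).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, erosion, footprint_rectangle
from skimage.registration import phase_cross_correlation

from .errors import EmptyResultError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.6


@dataclass
class LabelMask:
    """2-D integer label image; 0 is background, k > 0 is cell k.

    Parameters
    ----------
    grid : ndarray of int, shape (rows, cols)
        Label image. Row index is Y, column index is X (0-based).
    pixel_size_um : float
        Physical pixel size in micrometres per pixel.
    """

    grid: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ParameterError(f"label grid must be 2-D, got ndim={self.grid.ndim}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ParameterError(f"label grid must be integer-typed, got {self.grid.dtype}")
        if self.grid.size and self.grid.min() < 0:
            raise ParameterError("label grid contains negative labels")
        if not self.pixel_size_um > 0:
            raise ParameterError(f"pixel_size_um must be positive, got {self.pixel_size_um}")

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of nonzero labels present in the mask."""
        lab = np.unique(self.grid)
        return lab[lab > 0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def _make_footprint(radius: int, kind: str) -> np.ndarray:
    if kind == "disk":
        return disk(radius)
    if kind == "square":
        return footprint_rectangle((2 * radius + 1, 2 * radius + 1))
    raise ParameterError(f"unknown footprint kind {kind!r}; use 'disk' or 'square'")


def binarize_channel(
    image: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> np.ndarray:
    """Binarize a marker channel; pixels >= threshold become True.

    A constant image under Otsu yields an all-False mask with a logged
    warning rather than raising.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ParameterError("image contains non-finite values")
    if method == "fixed":
        if fixed_threshold is None:
            raise ParameterError("method='fixed' requires fixed_threshold")
        return image >= float(fixed_threshold)
    if method != "otsu":
        raise ParameterError(f"unknown binarization method {method!r}")
    if image.size == 0 or np.ptp(image) == 0:
        logger.warning("constant image passed to Otsu binarization; returning all-False mask")
        return np.zeros(image.shape, dtype=bool)
    return image >= threshold_otsu(image)


def _label_slices(grid: np.ndarray) -> dict[int, tuple[slice, slice]]:
    from scipy import ndimage

    slices = ndimage.find_objects(grid)
    out = {}
    for lab, sl in enumerate(slices, start=1):
        if sl is not None:
            out[lab] = sl
    return out


def donut_outline(
    mask: LabelMask,
    r_in_px: int = 2,
    r_out_px: int = 2,
    footprint: str = "disk",
) -> LabelMask:
    """Build per-cell ring regions: dilation(cell, r_out) minus erosion(cell, r_in).

    Pixels claimed by more than one ring are assigned to the cell whose
    nearest pixel is closest (ties broken toward the smaller label), so
    output rings are pairwise disjoint and output labels are a subset of
    input labels.
    """
    if r_in_px < 0 or r_out_px < 0:
        raise ParameterError("ring radii must be non-negative")
    if r_in_px == 0 and r_out_px == 0:
        raise ParameterError("r_in_px and r_out_px cannot both be zero")

    grid = mask.grid
    out = np.zeros_like(grid)
    if grid.size == 0 or not mask.labels.size:
        return LabelMask(out, mask.pixel_size_um)

    fp_out = _make_footprint(r_out_px, footprint) if r_out_px > 0 else None
    fp_in = _make_footprint(r_in_px, footprint) if r_in_px > 0 else None

    n_claims = np.zeros(grid.shape, dtype=np.int32)
    rings: dict[int, np.ndarray] = {}
    pad = r_out_px + 1
    for lab, (sy, sx) in _label_slices(grid).items():
        y0, y1 = max(sy.start - pad, 0), min(sy.stop + pad, grid.shape[0])
        x0, x1 = max(sx.start - pad, 0), min(sx.stop + pad, grid.shape[1])
        cell = grid[y0:y1, x0:x1] == lab
        dil = dilation(cell, fp_out) if fp_out is not None else cell
        ero = erosion(cell, fp_in) if fp_in is not None else cell
        ring_local = dil & ~ero
        ring = np.zeros(grid.shape, dtype=bool)
        ring[y0:y1, x0:x1] = ring_local
        rings[lab] = ring
        out[ring] = lab
        n_claims[ring] += 1

    contested = np.argwhere(n_claims > 1)
    if contested.size:
        trees = {
            lab: cKDTree(np.argwhere(grid == lab)) for lab in rings
        }
        for yx in contested:
            best = None
            for lab, ring in rings.items():
                if not ring[yx[0], yx[1]]:
                    continue
                d = trees[lab].query(yx)[0]
                # ties go to the smaller label (labels iterated in order)
                if best is None or d < best[0] - 1e-12:
                    best = (d, lab)
            out[yx[0], yx[1]] = best[1]
    return LabelMask(out, mask.pixel_size_um)


def overlap_fraction(
    region: LabelMask,
    marker: np.ndarray,
    region_kind: str = "whole",
) -> pd.DataFrame:
    """Per-label overlap fraction of a region mask with a binary marker.

    Returns a table with columns ``label, region_kind, area_px, overlap_px,
    fraction``; fraction = overlap pixels / region area, always in [0, 1].
    """
    marker = np.asarray(marker, dtype=bool)
    if marker.shape != region.shape:
        raise ParameterError(
            f"shape mismatch: region {region.shape} vs marker {marker.shape}"
        )
    labels = region.labels
    if labels.size == 0:
        return pd.DataFrame(
            columns=["label", "region_kind", "area_px", "overlap_px", "fraction"]
        )
    n = int(labels.max()) + 1
    area = np.bincount(region.grid.ravel(), minlength=n)
    overlap = np.bincount(region.grid[marker].ravel(), minlength=n)
    return pd.DataFrame(
        {
            "label": labels,
            "region_kind": region_kind,
            "area_px": area[labels],
            "overlap_px": overlap[labels],
            "fraction": overlap[labels] / area[labels],
        }
    )


def classify_positive(
    table: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Flag cells with fraction strictly greater than the threshold.

    The comparison is strict, so a fraction exactly at the threshold is
    negative.
    """
    if not 0 <= threshold <= 1:
        raise ParameterError(f"threshold must lie in [0, 1], got {threshold}")
    if "fraction" not in table.columns:
        raise ParameterError("table lacks a 'fraction' column; run overlap_fraction first")
    out = table.copy()
    out["positive"] = out["fraction"] > threshold
    return out


def percent_positive(table: pd.DataFrame) -> float:
    """100 x positives / scored cells."""
    if len(table) == 0:
        raise EmptyResultError("percent_positive is undefined on an empty score table")
    if "positive" not in table.columns:
        raise ParameterError("table lacks a 'positive' column; run classify_positive first")
    return 100.0 * float(table["positive"].sum()) / float(len(table))


def register_translation(moving: np.ndarray, fixed: np.ndarray) -> tuple[int, int]:
    """Integer (dy, dx) offset that best aligns `moving` onto `fixed`.

    Maximizes cross-correlation; shifting `moving` by the returned offset
    (np.roll semantics) registers it with `fixed`. Constant images cannot
    be registered and return (0, 0) with a warning.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ParameterError(f"shape mismatch: {moving.shape} vs {fixed.shape}")
    if np.ptp(moving) == 0 or np.ptp(fixed) == 0:
        logger.warning("constant image(s) passed to register_translation; returning (0, 0)")
        return (0, 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shift, _, _ = phase_cross_correlation(
            fixed, moving, upsample_factor=1, normalization=None
        )
    return (int(round(shift[0])), int(round(shift[1])))


def score_nuclear_marker(
    dapi: LabelMask,
    reporter: np.ndarray,
    marker: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Score a nuclear marker against reporter-positive nuclei.

    A nucleus is reporter-positive when its overlap fraction with the
    binarized reporter exceeds the threshold; among reporter-positive
    nuclei the marker is scored the same way, and the percentage uses the
    reporter-positive nuclei as denominator.
    """
    if not 0 <= threshold <= 1:
        raise ParameterError(f"threshold must lie in [0, 1], got {threshold}")
    rep = overlap_fraction(dapi, reporter, region_kind="nucleus")
    rep = rep.rename(columns={"fraction": "reporter_fraction", "overlap_px": "reporter_overlap_px"})
    mk = overlap_fraction(dapi, marker, region_kind="nucleus")
    table = rep.merge(mk[["label", "overlap_px", "fraction"]], on="label")
    table["reporter_positive"] = table["reporter_fraction"] > threshold
    table["positive"] = table["reporter_positive"] & (table["fraction"] > threshold)
    n_rep = int(table["reporter_positive"].sum())
    if n_rep == 0:
        raise EmptyResultError("no reporter-positive nuclei; percent positive is undefined")
    n_pos = int(table["positive"].sum())
    summary = {
        "region_kind": "nucleus",
        "threshold": threshold,
        "n_cells": n_rep,
        "n_positive": n_pos,
        "percent_positive": 100.0 * n_pos / n_rep,
    }
    return table, summary


@dataclass
class ScoreResult:
    """Output of the full per-pattern scoring pipeline."""

    table: pd.DataFrame
    summary: dict = field(default_factory=dict)


def score_pattern(
    mask: LabelMask,
    marker_image: np.ndarray,
    pattern: str,
    threshold: float = DEFAULT_THRESHOLD,
    ring_px: tuple[int, int] = (2, 2),
    binarize_method: str = "otsu",
    fixed_threshold: float | None = None,
    reporter_image: np.ndarray | None = None,
) -> ScoreResult:
    """End-to-end scoring for one marker pattern.

    membrane    -> donut ring regions scored against the marker
    cytoplasmic -> whole-cell regions scored against the marker
    nuclear     -> `mask` is a nuclei (DAPI) mask; requires `reporter_image`
    """
    marker_bin = binarize_channel(marker_image, binarize_method, fixed_threshold)
    if pattern == "membrane":
        region = donut_outline(mask, *ring_px)
        table = classify_positive(overlap_fraction(region, marker_bin, "donut"), threshold)
        kind = "donut"
    elif pattern == "cytoplasmic":
        table = classify_positive(overlap_fraction(mask, marker_bin, "whole"), threshold)
        kind = "whole"
    elif pattern == "nuclear":
        if reporter_image is None:
            raise ParameterError("nuclear pattern requires reporter_image")
        reporter_bin = binarize_channel(reporter_image, binarize_method, fixed_threshold)
        table, summary = score_nuclear_marker(mask, reporter_bin, marker_bin, threshold)
        return ScoreResult(table, summary)
    else:
        raise ParameterError(f"unknown pattern {pattern!r}")
    summary = {
        "region_kind": kind,
        "threshold": threshold,
        "n_cells": int(len(table)),
        "n_positive": int(table["positive"].sum()),
        "percent_positive": percent_positive(table),
    }
    return ScoreResult(table, summary)
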