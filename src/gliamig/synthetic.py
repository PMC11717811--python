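"""Seeded generators for every input the pipeline consumes, with ground truth.

All generators take one explicit integer seed and touch no global random
state; identical seeds give identical outputs. Noise-free parameter limits
reproduce the generating parameters exactly, which the test suite leans on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import sparse
from skimage.draw import ellipse
from skimage.morphology import dilation, disk, erosion

from .coloc import LabelMask
from .errors import CapacityError, ParameterError

MARKER_PATTERNS = ("membrane", "cytoplasmic", "nuclear")


# ---------------------------------------------------------------------------
# colocalization images
# ---------------------------------------------------------------------------

@dataclass
class ColocTruth:
    """Design of a synthetic two-channel colocalization scene."""

    n_cells: int
    true_positive_fraction: float
    marker_pattern: str = "cytoplasmic"
    pixel_size_um: float = 1.0
    image_shape: tuple[int, int] = (512, 512)
    cell_radius_px: tuple[float, float] = (5.0, 9.0)
    background_level: float = 0.1
    signal_level: float = 1.0
    noise_sigma: float = 0.05
    max_tries_per_cell: int = 500

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if not 0 <= self.true_positive_fraction <= 1:
            raise ParameterError("true_positive_fraction must lie in [0, 1]")
        if self.marker_pattern not in MARKER_PATTERNS:
            raise ParameterError(
                f"marker_pattern must be one of {MARKER_PATTERNS}, got {self.marker_pattern!r}"
            )
        if not self.pixel_size_um > 0:
            raise ParameterError("pixel_size_um must be positive")
        if self.cell_radius_px[0] < 1 or self.cell_radius_px[1] < self.cell_radius_px[0]:
            raise ParameterError("cell_radius_px must satisfy 1 <= lo <= hi")


class SimulatedColoc(NamedTuple):
    mask: LabelMask
    marker: np.ndarray
    reporter: np.ndarray
    truth: pd.DataFrame


def make_coloc_image(truth: ColocTruth, seed: int) -> SimulatedColoc:
    """Place non-overlapping labeled ellipses and paint a marker channel.

    Each cell's truth flag is an independent Bernoulli(true_positive_fraction)
    draw. The marker is bright on the cell's membrane ring, interior, or
    nucleus (per ``marker_pattern``) iff the flag is set, on top of Gaussian
    background noise. The reporter channel is bright inside every cell.
    Labels in the emitted mask are exactly 1..n_cells.
    """
    rng = np.random.default_rng(seed)
    h, w = truth.image_shape
    grid = np.zeros((h, w), dtype=np.uint16)
    occupied = np.zeros((h, w), dtype=bool)
    flags = rng.random(truth.n_cells) < truth.true_positive_fraction

    rows = []
    for k in range(1, truth.n_cells + 1):
        placed = False
        for _ in range(truth.max_tries_per_cell):
            a = rng.uniform(*truth.cell_radius_px)
            b = rng.uniform(*truth.cell_radius_px)
            theta = rng.uniform(0, np.pi)
            margin = int(np.ceil(max(a, b))) + 4
            if h - margin <= margin or w - margin <= margin:
                raise CapacityError("image too small for the configured cell radii")
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            rr, cc = ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
            # require a 2-px clear margin so neighboring rings stay separable
            rr_m, cc_m = ellipse(cy, cx, a + 2, b + 2, shape=(h, w), rotation=theta)
            if occupied[rr_m, cc_m].any():
                continue
            grid[rr, cc] = k
            occupied[rr_m, cc_m] = True
            rows.append(
                {
                    "label": k,
                    "cy_px": cy,
                    "cx_px": cx,
                    "a_px": a,
                    "b_px": b,
                    "theta_rad": theta,
                    "true_positive": bool(flags[k - 1]),
                }
            )
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place cell {k} after {truth.max_tries_per_cell} tries; "
                "reduce n_cells or enlarge the image"
            )

    marker = truth.background_level + rng.normal(0, truth.noise_sigma, size=(h, w))
    reporter = truth.background_level + rng.normal(0, truth.noise_sigma, size=(h, w))
    reporter[grid > 0] += truth.signal_level
    fp = disk(2)
    for row in rows:
        if not row["true_positive"]:
            continue
        cell = grid == row["label"]
        if truth.marker_pattern == "membrane":
            region = dilation(cell, fp) & ~erosion(cell, fp)
        elif truth.marker_pattern == "cytoplasmic":
            region = cell
        else:  # nuclear: the labeled ellipse is the nucleus
            region = cell
        marker[region] += truth.signal_level
    np.clip(marker, 0, None, out=marker)
    np.clip(reporter, 0, None, out=reporter)

    truth_table = pd.DataFrame(
        rows,
        columns=["label", "cy_px", "cx_px", "a_px", "b_px", "theta_rad", "true_positive"],
    )
    return SimulatedColoc(
        LabelMask(grid, truth.pixel_size_um),
        marker.astype(np.float32),
        reporter.astype(np.float32),
        truth_table,
    )


# ---------------------------------------------------------------------------
# time-lapse tracks
# ---------------------------------------------------------------------------

def make_timelapse(
    n_cells: int,
    mean_speed_um_h: float,
    sd_speed: float,
    interval_min: float,
    n_frames: int,
    seed: int,
) -> pd.DataFrame:
    """Constant-speed straight-line tracks sampled at a fixed frame interval.

    Per-cell speeds are drawn from N(mean, sd) truncated at zero (negative
    draws are clipped, preserving seed determinism); each cell gets a random
    heading. Columns: cell_id, frame, t_h, x_um, y_um, true_speed_um_h.
    """
    if n_cells < 0:
        raise ParameterError("n_cells must be >= 0")
    if sd_speed < 0:
        raise ParameterError("sd_speed must be >= 0")
    if not interval_min > 0:
        raise ParameterError("interval_min must be positive")
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    speeds = np.maximum(rng.normal(mean_speed_um_h, sd_speed, size=n_cells), 0.0)
    headings = rng.uniform(0, 2 * np.pi, size=n_cells)
    origins = rng.uniform(0, 1000.0, size=(n_cells, 2))
    t_h = np.arange(n_frames) * interval_min / 60.0

    frames = np.tile(np.arange(n_frames), n_cells)
    cells = np.repeat(np.arange(1, n_cells + 1), n_frames)
    tt = np.tile(t_h, n_cells)
    sp = np.repeat(speeds, n_frames)
    hd = np.repeat(headings, n_frames)
    ox = np.repeat(origins[:, 0], n_frames) if n_cells else np.array([])
    oy = np.repeat(origins[:, 1], n_frames) if n_cells else np.array([])
    return pd.DataFrame(
        {
            "cell_id": cells,
            "frame": frames,
            "t_h": tt,
            "x_um": ox + sp * tt * np.cos(hd),
            "y_um": oy + sp * tt * np.sin(hd),
            "true_speed_um_h": sp,
        }
    )


# ---------------------------------------------------------------------------
# hierarchical explant experiments
# ---------------------------------------------------------------------------

@dataclass
class ExplantDesign:
    """Design of a synthetic explant migration experiment.

    ``multipliers`` maps treatment -> (lateral, radial, count_fold) or
    (lateral, radial, count_fold, cortex_count_fold); the control row must
    be all ones. Random-effect sigmas are on the log scale. Slices are
    nested in litters; each slice receives one treatment, rotated across
    litters so every treatment appears in every litter position over the
    design.
    """

    n_litters: int
    slices_per_litter: int
    cells_per_slice: int
    treatments: tuple[str, ...] = ("control",)
    baseline_lateral_um: float = 156.0
    baseline_radial_um: float = 200.0
    baseline_cc_to_ctx_um: float = 120.0
    baseline_count: float = 100.0
    baseline_count_cortex: float = 60.0
    multipliers: dict = field(default_factory=dict)
    sigma_litter: float = 0.1
    sigma_slice: float = 0.1
    sigma_cell: float = 0.3
    duration_h: float = 168.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_litters < 2:
            raise ParameterError("need >= 2 litters for variance components to be estimable")
        if self.slices_per_litter < 1 or self.cells_per_slice < 1:
            raise ParameterError("slices_per_litter and cells_per_slice must be >= 1")
        if "control" not in self.treatments:
            raise ParameterError("treatments must include 'control'")
        for s in (self.sigma_litter, self.sigma_slice, self.sigma_cell):
            if s < 0:
                raise ParameterError("sigmas must be >= 0")
        self.multipliers = dict(self.multipliers)
        self.multipliers.setdefault("control", (1.0, 1.0, 1.0))
        for tr in self.multipliers:
            if tr not in self.treatments:
                raise ParameterError(f"multiplier given for unknown treatment {tr!r}")
        for tr in self.treatments:
            mult = self.multipliers.setdefault(tr, (1.0, 1.0, 1.0))
            if len(mult) not in (3, 4) or any(m <= 0 for m in mult):
                raise ParameterError(
                    f"multipliers[{tr!r}] must be 3 or 4 positive numbers, got {mult}"
                )
        if tuple(self.multipliers["control"][:3]) != (1.0, 1.0, 1.0):
            raise ParameterError("control multipliers must be (1, 1, 1)")

    def count_folds(self, treatment: str) -> tuple[float, float]:
        mult = self.multipliers[treatment]
        fold = float(mult[2])
        return fold, float(mult[3]) if len(mult) == 4 else fold


class SimulatedExplant(NamedTuple):
    records: pd.DataFrame
    counts: pd.DataFrame
    truth: dict


def make_explant_experiment(design: ExplantDesign) -> SimulatedExplant:
    """Generate per-cell migration endpoints and per-slice migrated counts.

    Log-displacements are log(baseline) + log(multiplier) + litter effect +
    slice effect + cell noise, exponentiated; independent effect chains per
    outcome. Counts are Poisson with mean baseline_count x count_fold.
    """
    rng = np.random.default_rng(design.seed)
    treatments = list(design.treatments)
    n_t = len(treatments)

    outcome_base = {
        "lateral": design.baseline_lateral_um,
        "radial": design.baseline_radial_um,
        "cc_to_ctx": design.baseline_cc_to_ctx_um,
    }
    mult_index = {"lateral": 0, "radial": 1, "cc_to_ctx": 1}  # cc_to_ctx shares radial fold

    rec_rows = []
    count_rows = []
    cell_counter = 0
    for li in range(design.n_litters):
        litter_id = f"L{li + 1:02d}"
        litter_eff = {o: rng.normal(0, design.sigma_litter) for o in outcome_base}
        litter_eff_count = rng.normal(0, design.sigma_litter)
        for si in range(design.slices_per_litter):
            slice_id = f"{litter_id}S{si + 1:02d}"
            treatment = treatments[(li + si) % n_t]
            slice_eff = {o: rng.normal(0, design.sigma_slice) for o in outcome_base}
            mult = design.multipliers[treatment]
            disp = {}
            for o, base in outcome_base.items():
                log_mu = (
                    np.log(base)
                    + np.log(float(mult[mult_index[o]]))
                    + litter_eff[o]
                    + slice_eff[o]
                )
                disp[o] = np.exp(log_mu + rng.normal(0, design.sigma_cell, design.cells_per_slice))
            x_sign = rng.choice([-1.0, 1.0], size=design.cells_per_slice)
            for ci in range(design.cells_per_slice):
                cell_counter += 1
                rec_rows.append(
                    {
                        "cell_id": f"C{cell_counter:05d}",
                        "litter": litter_id,
                        "slice": slice_id,
                        "treatment": treatment,
                        "x1": 0.0,
                        "y1": 0.0,
                        "x2": x_sign[ci] * disp["lateral"][ci],
                        "y2": disp["radial"][ci],
                        "t_h": design.duration_h,
                        "cc_to_ctx": disp["cc_to_ctx"][ci],
                    }
                )
            fold_out, fold_ctx = design.count_folds(treatment)
            mean_scale = np.exp(litter_eff_count)
            count_rows.append(
                {
                    "litter": litter_id,
                    "slice": slice_id,
                    "treatment": treatment,
                    "n_outside": int(
                        rng.poisson(design.baseline_count * fold_out * mean_scale)
                    ),
                    "n_cortex": int(
                        rng.poisson(design.baseline_count_cortex * fold_ctx * mean_scale)
                    ),
                }
            )

    records = pd.DataFrame(rec_rows)
    counts = pd.DataFrame(count_rows)
    truth = {
        "multipliers": {t: tuple(float(m) for m in design.multipliers[t]) for t in treatments},
        "baselines": dict(outcome_base),
        "baseline_count": design.baseline_count,
        "baseline_count_cortex": design.baseline_count_cortex,
        "sigma_litter": design.sigma_litter,
        "sigma_slice": design.sigma_slice,
        "sigma_cell": design.sigma_cell,
        "seed": design.seed,
    }
    return SimulatedExplant(records, counts, truth)


# ---------------------------------------------------------------------------
# count matrices with planted QC failures
# ---------------------------------------------------------------------------

FAILURE_MODES = ("low_features", "high_features", "high_mito")


def make_count_matrix(
    n_cells: int,
    n_genes: int,
    planted_qc_failures: dict[str, int] | None = None,
    seed: int = 0,
    n_mito_genes: int = 13,
    mito_prefix: str = "mt-",
):
    """Sparse genes x cells count matrix with cells violating exactly one QC rule.

    Returns (CountMatrix, truth DataFrame). Truth columns: barcode,
    planted_failure ('none' or a failure mode), survives.
    """
    from .expression_qc import CountMatrix

    planted = dict(planted_qc_failures or {})
    for mode in planted:
        if mode not in FAILURE_MODES:
            raise ParameterError(f"unknown failure mode {mode!r}; use one of {FAILURE_MODES}")
        if planted[mode] < 0:
            raise ParameterError("failure counts must be >= 0")
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    if n_cells < 0:
        raise ParameterError("n_cells must be >= 0")
    n_fail = sum(planted.values())
    if n_fail > n_cells:
        raise ParameterError(f"{n_fail} planted failures exceed n_cells={n_cells}")
    if planted.get("high_features", 0) and n_genes <= 5000:
        raise ParameterError("planting high_features failures requires n_genes > 5000")
    n_mito = min(n_mito_genes, n_genes)
    n_regular = n_genes - n_mito
    if n_regular < 300 and n_cells > n_fail:
        raise ParameterError("need >= 300 non-mitochondrial genes for passing cells")

    rng = np.random.default_rng(seed)
    genes = np.array(
        [f"{mito_prefix}gene{i}" for i in range(n_mito)]
        + [f"gene{i}" for i in range(n_regular)]
    )
    barcodes = np.array([f"cell{i:05d}" for i in range(n_cells)])

    modes = ["none"] * n_cells
    idx = rng.permutation(n_cells)
    pos = 0
    for mode in FAILURE_MODES:
        for _ in range(planted.get(mode, 0)):
            modes[idx[pos]] = mode
            pos += 1

    rows, cols, vals = [], [], []

    def add_cell(j: int, feat_idx: np.ndarray, counts: np.ndarray) -> None:
        rows.extend(feat_idx.tolist())
        cols.extend([j] * len(feat_idx))
        vals.extend(counts.tolist())

    mito_idx = np.arange(n_mito)
    regular_idx = np.arange(n_mito, n_genes)
    truth_rows = []
    for j in range(n_cells):
        mode = modes[j]
        if mode == "low_features":
            n_feat = int(rng.integers(10, min(150, n_regular)))
            feats = rng.choice(regular_idx, size=n_feat, replace=False)
            counts = 1 + rng.poisson(1.0, n_feat)
        elif mode == "high_features":
            lo, hi = 5001, min(6000, n_genes) + 1
            n_feat = int(rng.integers(lo, hi)) if lo < hi else n_genes
            feats = rng.choice(np.arange(n_genes), size=n_feat, replace=False)
            # keep the mito share of counts low so only one rule is broken
            counts = 1 + rng.poisson(0.5, n_feat)
        elif mode == "high_mito":
            n_feat = int(rng.integers(300, min(800, n_regular)))
            feats = rng.choice(regular_idx, size=n_feat, replace=False)
            counts = 1 + rng.poisson(1.0, n_feat)
            total = counts.sum()
            n_m = min(3, n_mito)
            mito_feats = mito_idx[:n_m]
            # mito counts sized to push the fraction well past 0.25
            mito_counts = np.full(n_m, int(np.ceil(total / n_m)) + 1)
            feats = np.concatenate([feats, mito_feats])
            counts = np.concatenate([counts, mito_counts])
        else:
            n_feat = int(rng.integers(300, min(2000, n_regular)))
            feats = rng.choice(regular_idx, size=n_feat, replace=False)
            counts = 1 + rng.poisson(1.0, n_feat)
            if n_mito:
                total = counts.sum()
                mito_count = max(1, int(0.05 * total))
                feats = np.concatenate([feats, mito_idx[:1]])
                counts = np.concatenate([counts, [mito_count]])
        add_cell(j, np.asarray(feats), np.asarray(counts))
        truth_rows.append(
            {"barcode": barcodes[j], "planted_failure": mode, "survives": mode == "none"}
        )

    matrix = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_genes, n_cells), dtype=np.int64
    )
    truth = pd.DataFrame(truth_rows, columns=["barcode", "planted_failure", "survives"])
    return CountMatrix(matrix, genes, barcodes, (mito_prefix,)), truth
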