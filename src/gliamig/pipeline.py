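"""Config-driven end-to-end runs and the machine-readable run report.

A run is fully determined by its config plus seed: every stage derives its
randomness from the run seed, and every default actually used is echoed
into the report so no silent parameters exist.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__, coloc, expression_qc, gated_stats, migration, synthetic
from .errors import ComputationError, InputError, ParameterError

REPORT_REQUIRED_KEYS = ("package_version", "seed", "parameters", "stages", "warnings")

_KNOWN_STAGES = ("simulate", "coloc", "migrate", "stats", "qc")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    out_dir: str
    seed: int = 0
    simulate: dict | None = None
    coloc: dict | None = None
    migrate: dict | None = None
    stats: dict | None = None
    qc: dict | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ParameterError("seed must be an integer")
        for name in _KNOWN_STAGES:
            block = getattr(self, name)
            if block is not None and not isinstance(block, dict):
                raise ParameterError(f"config block {name!r} must be a mapping")
        if all(getattr(self, name) is None for name in _KNOWN_STAGES):
            raise ParameterError("config enables no stages")
        threshold = (self.coloc or {}).get("threshold")
        if threshold is not None and not 0 <= threshold <= 1:
            raise ParameterError("coloc.threshold must lie in [0, 1]")
        alpha = (self.stats or {}).get("alpha")
        if alpha is not None and not 0 < alpha < 1:
            raise ParameterError("stats.alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"out_dir", "seed", *_KNOWN_STAGES}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ParameterError("config requires out_dir")
        return cls(**raw)


def _require_inputs(config: RunConfig) -> None:
    """Fail on missing input paths before any computation runs."""
    blocks = [(n, getattr(config, n)) for n in ("coloc", "migrate", "stats", "qc")]
    for name, block in blocks:
        if not block:
            continue
        for key, value in block.items():
            if key.endswith(("_path", "_csv", "_tif", "_mtx")) and value is not None:
                if not Path(value).exists():
                    raise InputError(f"{name}.{key}: input not found: {value}")


def _stage_simulate(config: RunConfig, out: Path, report: dict) -> dict:
    block = config.simulate or {}
    produced: dict = {}
    seeds = {}
    if "coloc" in block:
        params = dict(block["coloc"])
        seed = params.pop("seed", config.seed)
        seeds["coloc"] = seed
        truth = synthetic.ColocTruth(**params)
        sim = synthetic.make_coloc_image(truth, seed)
        tifffile.imwrite(out / "sim_mask.tif", sim.mask.grid.astype(np.uint16))
        tifffile.imwrite(out / "sim_marker.tif", sim.marker.astype(np.float32))
        tifffile.imwrite(out / "sim_reporter.tif", sim.reporter.astype(np.float32))
        sim.truth.to_csv(out / "sim_coloc_truth.csv", index=False)
        with open(out / "sim_coloc_truth.json", "w") as fh:
            json.dump(
                {
                    "n_cells": truth.n_cells,
                    "true_positive_fraction": truth.true_positive_fraction,
                    "marker_pattern": truth.marker_pattern,
                    "pixel_size_um": truth.pixel_size_um,
                    "seed": seed,
                },
                fh,
                indent=2,
            )
        produced["coloc"] = {
            "mask": str(out / "sim_mask.tif"),
            "marker": str(out / "sim_marker.tif"),
            "reporter": str(out / "sim_reporter.tif"),
            "pattern": truth.marker_pattern,
            "pixel_size_um": truth.pixel_size_um,
        }
    if "timelapse" in block:
        params = dict(block["timelapse"])
        seed = params.pop("seed", config.seed)
        seeds["timelapse"] = seed
        tracks = synthetic.make_timelapse(seed=seed, **params)
        tracks.to_csv(out / "sim_tracks.csv", index=False)
        produced["timelapse"] = {"tracks": str(out / "sim_tracks.csv")}
    if "explant" in block:
        params = dict(block["explant"])
        params.setdefault("seed", config.seed)
        if "treatments" in params:
            params["treatments"] = tuple(params["treatments"])
        if "multipliers" in params:
            params["multipliers"] = {
                k: tuple(v) for k, v in params["multipliers"].items()
            }
        seeds["explant"] = params["seed"]
        design = synthetic.ExplantDesign(**params)
        sim = synthetic.make_explant_experiment(design)
        sim.records.to_csv(out / "sim_records.csv", index=False)
        sim.counts.to_csv(out / "sim_counts.csv", index=False)
        with open(out / "sim_explant_truth.json", "w") as fh:
            json.dump(sim.truth, fh, indent=2)
        produced["explant"] = {
            "records": str(out / "sim_records.csv"),
            "counts": str(out / "sim_counts.csv"),
        }
    if "counts" in block:
        params = dict(block["counts"])
        seed = params.pop("seed", config.seed)
        seeds["counts"] = seed
        matrix, truth = synthetic.make_count_matrix(seed=seed, **params)
        paths = expression_qc.write_counts_mtx(matrix, out / "sim_counts_mtx")
        truth.to_csv(out / "sim_counts_truth.csv", index=False)
        produced["counts"] = paths
    report["seeds"] = seeds
    return produced


def _stage_coloc(config: RunConfig, out: Path, simulated: dict) -> dict:
    block = dict(config.coloc or {})
    sim = simulated.get("coloc", {})
    mask_path = block.get("mask_tif") or sim.get("mask")
    marker_path = block.get("marker_tif") or sim.get("marker")
    if mask_path is None or marker_path is None:
        raise InputError("coloc stage needs mask_tif and marker_tif (or a simulate block)")
    pattern = block.get("pattern") or sim.get("pattern", "cytoplasmic")
    pixel_size = block.get("pixel_size_um") or sim.get("pixel_size_um", 1.0)
    mask = coloc.LabelMask(tifffile.imread(mask_path).astype(np.int64), pixel_size)
    marker = tifffile.imread(marker_path)
    reporter_path = block.get("reporter_tif") or sim.get("reporter")
    reporter = tifffile.imread(reporter_path) if reporter_path else None
    result = coloc.score_pattern(
        mask,
        marker,
        pattern,
        threshold=block.get("threshold", coloc.DEFAULT_THRESHOLD),
        ring_px=tuple(block.get("ring_px", (2, 2))),
        binarize_method=block.get("binarize_method", "otsu"),
        fixed_threshold=block.get("fixed_threshold"),
        reporter_image=reporter,
    )
    result.table.to_csv(out / "coloc_scores.csv", index=False)
    with open(out / "coloc_summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2)
    return result.summary


def _stage_migrate(config: RunConfig, out: Path, simulated: dict) -> dict:
    block = dict(config.migrate or {})
    points_path = block.get("points_csv") or simulated.get("explant", {}).get("records")
    if points_path is None:
        raise InputError("migrate stage needs points_csv (or a simulate.explant block)")
    points = pd.read_csv(points_path)
    derived = migration.derive_records(points)
    summary: dict = {"n_records": int(len(derived))}
    if "curve_points" in block:
        curve = migration.smooth_white_matter_curve(
            block["curve_points"],
            smoothing=block.get("curve_smoothing", 0.0),
            cortex_positive_y=block.get("cortex_positive_y", True),
        )
        derived = migration.cc_to_ctx_distances(derived, curve)
        summary["n_in_cortex"] = int(derived["in_cortex"].sum())
    derived.to_csv(out / "migration_records.csv", index=False)
    summary["records"] = str(out / "migration_records.csv")
    if "reporter_tif" in block:
        image = tifffile.imread(block["reporter_tif"])
        cortex = None
        if block.get("cortex_mask_tif"):
            cortex = tifffile.imread(block["cortex_mask_tif"]).astype(bool)
        counts = migration.count_migrated(
            image,
            tuple(block.get("implant_center_um", (0.0, 0.0))),
            block.get("implant_radius_um", 500.0),
            cortex,
            block.get("min_area_px", 20),
            block.get("pixel_size_um", 1.0),
        )
        summary["counts"] = counts
    return summary


def _stage_stats(config: RunConfig, out: Path, simulated: dict, migrate_summary: dict) -> dict:
    block = dict(config.stats or {})
    records_path = (
        block.get("records_csv")
        or migrate_summary.get("records")
        or simulated.get("explant", {}).get("records")
    )
    if records_path is None:
        raise InputError("stats stage needs records_csv (or earlier stages producing one)")
    records = pd.read_csv(records_path)
    alpha = block.get("alpha", gated_stats.DEFAULT_ALPHA)
    families = None
    if "families" in block:
        families = gated_stats.TreatmentFamilies(
            {k: tuple(v) for k, v in block["families"].items()}
        )
    outcomes = block.get("outcomes", ["net", "lateral", "radial"])
    summary: dict = {"alpha": alpha, "outcomes": {}}
    for outcome in outcomes:
        model = gated_stats.fit_migration_model(records, outcome)
        gated = gated_stats.family_gate(model, families, alpha)
        gated.family_table.to_csv(out / f"stats_{outcome}_families.csv", index=False)
        gated.wald_table.to_csv(out / f"stats_{outcome}_wald.csv", index=False)
        summary["outcomes"][outcome] = {
            "families": gated.family_table.to_dict(orient="records"),
            "wald": gated.wald_table.to_dict(orient="records"),
            "warnings": gated.warnings,
            "model": model.summary(),
        }
    counts_path = block.get("counts_csv") or simulated.get("explant", {}).get("counts")
    if counts_path:
        counts = pd.read_csv(counts_path)
        for col in ("n_outside", "n_cortex"):
            if col in counts.columns:
                model = gated_stats.fit_count_model(counts, col)
                summary["outcomes"][f"count_{col}"] = {"model": model.summary()}
    return summary


def _stage_qc(config: RunConfig, out: Path, simulated: dict) -> dict:
    block = dict(config.qc or {})
    sim = simulated.get("counts", {})
    if block.get("counts_csv"):
        matrix = expression_qc.read_counts_csv(
            block["counts_csv"], tuple(block.get("mito_prefixes", ("mt-",)))
        )
    elif block.get("matrix_mtx") or sim:
        matrix = expression_qc.read_counts_mtx(
            block.get("matrix_mtx") or sim["matrix"],
            block.get("genes_csv") or sim["genes"],
            block.get("barcodes_csv") or sim["barcodes"],
            tuple(block.get("mito_prefixes", ("mt-",))),
        )
    else:
        raise InputError("qc stage needs counts_csv or matrix_mtx (or a simulate.counts block)")
    filtered, report = expression_qc.qc_filter(
        matrix,
        block.get("min_features", 200),
        block.get("max_features", 5000),
        block.get("max_mito", 0.25),
    )
    expression_qc.write_counts_mtx(filtered, out / "qc_filtered")
    normed = expression_qc.lognormalize(filtered, block.get("scale", expression_qc.DEFAULT_SCALE))
    report["normalized_nnz"] = int(normed.nnz)
    if "cluster_labels" in block and "target_cluster" in block:
        markers = expression_qc.marker_stats(
            normed, block["cluster_labels"], block["target_cluster"], list(filtered.genes)
        )
        markers.to_csv(out / "qc_markers.csv", index=False)
        report["markers_csv"] = str(out / "qc_markers.csv")
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write report.json.

    Stage order is simulate -> coloc -> migrate -> stats -> qc; a stage
    failure aborts the run with an error naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _require_inputs(config)
    report: dict = {
        "package_version": __version__,
        "python_version": platform.python_version(),
        "seed": int(config.seed),
        "parameters": {name: getattr(config, name) for name in _KNOWN_STAGES},
        "stages": {},
        "warnings": [],
    }
    simulated: dict = {}
    migrate_summary: dict = {}
    stage_fns = [
        ("simulate", lambda: _stage_simulate(config, out, report)),
        ("coloc", lambda: _stage_coloc(config, out, simulated)),
        ("migrate", lambda: _stage_migrate(config, out, simulated)),
        ("stats", lambda: _stage_stats(config, out, simulated, migrate_summary)),
        ("qc", lambda: _stage_qc(config, out, simulated)),
    ]
    for name, fn in stage_fns:
        if getattr(config, name) is None:
            continue
        try:
            result = fn()
        except (ParameterError, InputError):
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise ComputationError(f"stage {name!r} failed: {exc}") from exc
        report["stages"][name] = result
        if name == "simulate":
            simulated = result
        if name == "migrate":
            migrate_summary = result
    write_report(report, out / "report.json")
    return report


def write_report(report: dict, path) -> dict:
    """Schema-check, serialize, and round-trip-verify the run report."""
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise ParameterError(f"report lacks required keys: {missing}")
    if not isinstance(report["warnings"], list):
        raise ParameterError("report['warnings'] must be a list")

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, tuple):
            return list(obj)
        raise TypeError(f"unserializable object of type {type(obj)}")

    text = json.dumps(report, indent=2, sort_keys=True, default=_default)
    Path(path).write_text(text)
    reloaded = json.loads(text)
    if json.dumps(reloaded, sort_keys=True) != json.dumps(
        json.loads(text), sort_keys=True
    ):
        raise ComputationError("report does not round-trip losslessly")
    return reloaded


def config_to_yaml(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
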