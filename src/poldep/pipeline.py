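"""End-to-end orchestration: simulate -> quantify -> matrix -> network.

A run is fully described by a :class:`RunConfig` and a single seed; all
per-field randomness derives hierarchically from it, so reruns are
byte-identical and individual stages can be reproduced in isolation.
Large studies are streamed field by field (one stack in memory at a
time); writing the TIFF stacks to disk is optional.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .depmatrix import (build_matrix, neto_shift_test, normalize_to_controls,
                        summarize_all)
from .design import (DEFAULT_DELETIONS, DEFAULT_MARKERS, StudyDesign,
                     build_truth_table)
from .network import export_network, find_loops, matrix_to_edges
from .quantify import QuantifyParams, measurements_to_frame, quantify_field
from .synthgen import FieldParams, NoiseParams, iter_study_fields, read_stack

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists field-level problems."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    markers: tuple[str, ...] = DEFAULT_MARKERS
    deletions: tuple[str, ...] = DEFAULT_DELETIONS
    cells_per_arm: int = 100
    fields_per_combination: int = 10
    truth: str | dict = "null"
    # imaging geometry
    field_shape: tuple[int, int] = (256, 256)
    pixel_size_xy: float = 0.1
    n_z: int = 31
    z_step: float = 0.2
    # noise
    psf_sigma: float = 0.15
    poisson_scale: float = 1.0
    read_sigma: float = 2.0
    background_offset: float = 100.0
    # statistics
    alpha: float = 0.05
    min_effect: float = 0.10
    min_cells: int = 100
    matrix_statistic: str = "mean"
    roi_diameter: float = 3.0
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None
    write_images: bool = False

    def design(self) -> StudyDesign:
        return StudyDesign(markers=tuple(self.markers),
                           deletions=tuple(self.deletions),
                           cells_per_arm=self.cells_per_arm,
                           fields_per_combination=self.fields_per_combination)

    def field_params(self) -> FieldParams:
        return FieldParams(shape=tuple(self.field_shape),
                           pixel_size_xy=self.pixel_size_xy,
                           n_z=self.n_z, z_step=self.z_step)

    def noise_params(self) -> NoiseParams:
        return NoiseParams(psf_sigma=self.psf_sigma,
                           poisson_scale=self.poisson_scale,
                           read_sigma=self.read_sigma,
                           background_offset=self.background_offset)

    def quantify_params(self) -> QuantifyParams:
        return QuantifyParams(roi_diameter=self.roi_diameter)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["markers"] = list(d["markers"])
        d["deletions"] = list(d["deletions"])
        d["field_shape"] = list(d["field_shape"])
        return d


def validate_config(config: dict | RunConfig | None) -> RunConfig:
    """Fill defaults and check consistency; raises :class:`ConfigError`
    with the full error list (never returns a partially-defaulted config
    on error)."""
    if config is None:
        config = {}
    if isinstance(config, RunConfig):
        data = config.to_dict()
    else:
        data = dict(config)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    errors = [f"unknown config field: {k}" for k in data if k not in known]
    try:
        cfg = RunConfig(**{k: v for k, v in data.items() if k in known})
    except (TypeError, ValueError) as exc:
        raise ConfigError(errors + [str(exc)])

    def check(cond, msg):
        if not cond:
            errors.append(msg)

    check(cfg.cells_per_arm >= 1, "cells_per_arm: must be >= 1")
    check(cfg.fields_per_combination >= 1,
          "fields_per_combination: must be >= 1")
    check(cfg.n_z >= 1, "n_z: must be >= 1")
    check(cfg.z_step > 0, "z_step: must be > 0")
    check(cfg.pixel_size_xy > 0, "pixel_size_xy: must be > 0")
    check(len(cfg.field_shape) == 2 and min(cfg.field_shape) >= 32,
          "field_shape: must be two dimensions of >= 32 px")
    check(0 < cfg.alpha < 1, "alpha: must be in (0, 1)")
    check(cfg.min_effect >= 0, "min_effect: must be >= 0")
    check(cfg.min_cells >= 1, "min_cells: must be >= 1")
    check(cfg.matrix_statistic in ("mean", "max"),
          "matrix_statistic: must be 'mean' or 'max'")
    check(cfg.roi_diameter > 0, "roi_diameter: must be > 0")
    check(cfg.read_sigma >= 0, "read_sigma: must be >= 0")
    check(cfg.poisson_scale >= 0, "poisson_scale: must be >= 0")
    if errors:
        raise ConfigError(errors)
    if cfg.alpha > 0.1:
        log.warning("alpha = %.3g is unusually permissive", cfg.alpha)
    cfg.markers = tuple(cfg.markers)
    cfg.deletions = tuple(cfg.deletions)
    cfg.field_shape = tuple(cfg.field_shape)
    return cfg


def full_scale_config(seed: int = 0, **overrides) -> RunConfig:
    """The full-study preset: 9 markers x 10 deletions (81 combinations,
    self-pairs impossible), 120 cells per arm over 15 fields each, at a
    coarser 0.2 um/px sampling to keep a full run tractable on one CPU."""
    base = dict(cells_per_arm=120, fields_per_combination=15,
                field_shape=(320, 320), pixel_size_xy=0.2, seed=seed)
    base.update(overrides)
    return validate_config(base)


def quantify_cells(config: RunConfig,
                   collect_annotations: bool = False):
    """Simulate and measure every field; returns ``(cells, counts[,
    annotations])`` where ``cells`` has one row per analysed cell and
    ``counts`` one row per field of QC bookkeeping."""
    design = config.design()
    truth = build_truth_table(design, config.truth, seed=config.seed)
    qp = config.quantify_params()
    frames, count_rows, ann = [], [], []
    out = Path(config.out_dir) if (config.out_dir
                                   and config.write_images) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for stack in iter_study_fields(design, truth,
                                   noise=config.noise_params(),
                                   params=config.field_params(),
                                   seed=config.seed):
        fq = quantify_field(stack, qp)
        frames.append(measurements_to_frame(fq.measurements))
        count_rows.append({
            "field_id": stack.field_id, "marker": stack.marker,
            "deletion": stack.deletion, "n_segmented": fq.n_segmented,
            "n_analysed": fq.n_analysed, "n_excluded": fq.n_excluded,
        })
        if collect_annotations:
            ann.append(stack.annotation_frame())
        if out is not None:
            from .synthgen import write_stack
            write_stack(stack, out / f"{stack.field_id}.tif")
    cells = pd.concat(frames, ignore_index=True)
    counts = pd.DataFrame(count_rows)
    if collect_annotations:
        return cells, counts, pd.concat(ann, ignore_index=True)
    return cells, counts


def run_all(config: dict | RunConfig | None = None) -> dict:
    """Full pipeline; returns the run report (and writes outputs when
    ``config.out_dir`` is set)."""
    cfg = validate_config(config)
    cells, counts = quantify_cells(cfg)
    normalized = normalize_to_controls(cells, statistic=cfg.matrix_statistic)
    entries = summarize_all(normalized, min_cells=cfg.min_cells)
    matrix = build_matrix(entries, alpha=cfg.alpha,
                          min_effect=cfg.min_effect)
    neto = neto_shift_test(normalized, alpha=cfg.alpha)
    edges = matrix_to_edges(matrix, neto)
    loops = find_loops(edges)

    arm_counts = normalized.groupby(
        ["marker", "deletion", "genotype"]).size()
    report = {
        "poldep_version": __version__,
        "config": cfg.to_dict(),
        "n_fields": int(len(counts)),
        "n_segmented": int(counts["n_segmented"].sum()),
        "n_analysed": int(counts["n_analysed"].sum()),
        "n_excluded": int(counts["n_excluded"].sum()),
        "n_cells_normalized": int(len(normalized)),
        "n_combinations": int(matrix.groupby(
            ["marker", "deletion"]).ngroups),
        "min_arm_size": int(arm_counts.min()) if len(arm_counts) else 0,
        "arms_below_min_cells": int((arm_counts < cfg.min_cells).sum()),
        "calls": matrix["call"].value_counts().to_dict(),
        "neto_shifted": int(neto["shifted"].sum()),
        "n_edges": len(edges),
        "loops": {},
    }
    for loop in loops:
        report["loops"][loop.loop_class] = report["loops"].get(
            loop.loop_class, 0) + 1

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cells.to_csv(out / "cells.csv", index=False)
        counts.to_csv(out / "field_counts.csv", index=False)
        matrix.to_csv(out / "matrix.csv", index=False)
        neto.to_csv(out / "neto.csv", index=False)
        export_network(edges, loops, out / "net.tsv", "tsv")
        export_network(edges, loops, out / "net.dot", "dot")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return report


def quantify_manifest(manifest_path: str | Path,
                      params: QuantifyParams = QuantifyParams()
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure a study previously written to disk (manifest + TIFFs)."""
    mpath = Path(manifest_path)
    manifest = pd.read_csv(mpath)
    frames, count_rows = [], []
    for _, row in manifest.iterrows():
        stack = read_stack(mpath.parent / row["path"],
                           pixel_size_xy=row["pixel_size_xy"],
                           z_step=row["z_step"], field_id=row["field_id"],
                           marker=row["marker"], deletion=row["deletion"])
        fq = quantify_field(stack, params)
        frames.append(measurements_to_frame(fq.measurements))
        count_rows.append({
            "field_id": stack.field_id, "marker": stack.marker,
            "deletion": stack.deletion, "n_segmented": fq.n_segmented,
            "n_analysed": fq.n_analysed, "n_excluded": fq.n_excluded,
        })
    return (pd.concat(frames, ignore_index=True),
            pd.DataFrame(count_rows))
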