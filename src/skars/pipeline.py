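"""One-command orchestration of the sensor-analysis pipeline.

Chains the stages in order — input acquisition (synthetic cohort, trace
CSV, or multi-channel TIFF movie), segmentation and tracking when starting
from images, trace quality control, response features and responder
classification, population summaries, optional marker-quadrant analysis,
and model-based kinase-activity inference — writing every intermediate to
disk so each stage is independently re-runnable and testable.  Outputs are
byte-identical for identical (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from skars import segment as seg
from skars import traces as tr
from skars.model import (
    SensorModelParams,
    build_calibration,
    fit_activity_timecourse,
    infer_activity_steady,
    simulate_relocation,
    steady_state_ratio,
)
from skars.synth import (
    CohortSpec,
    FrameSpec,
    generate_cohort,
    render_frames,
    simulate_cohort_traces,
    spec_with,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline", "segment_movie"]


class ConfigError(ValueError):
    """The pipeline configuration is inconsistent."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Pipeline inputs, analysis windows and output location.

    Exactly one input source must be set: ``synthetic`` (a
    :class:`~skars.synth.CohortSpec`), ``traces_csv`` (a tidy trace table),
    or ``images`` (mapping of channel name to a multi-page TIFF path).  In
    synthetic mode ``render_images=True`` routes the data through the full
    imaging + segmentation path instead of emitting traces directly.
    """

    out_dir: str | Path = "skars_run"
    seed: int = 0
    synthetic: CohortSpec | None = None
    render_images: bool = False
    frame_spec: FrameSpec | None = None
    traces_csv: str | Path | None = None
    images: Mapping[str, str] | None = None
    frame_interval_min: float = 1.0
    stim_time: float | None = None
    initial_window: tuple[float, float] = (3.0, 5.0)
    theta: float | str = 0.2
    control_csv: str | Path | None = None
    slow_factor: float = 1.5
    qc: tr.QCConfig = field(default_factory=tr.QCConfig)
    model_params: SensorModelParams = field(default_factory=SensorModelParams)
    baseline_activity: float = 0.2
    marker_threshold: float | str = "otsu"

    def __post_init__(self) -> None:
        sources = [self.synthetic is not None, self.traces_csv is not None, self.images is not None]
        if sum(sources) != 1:
            raise ConfigError(
                "exactly one input source (synthetic, traces_csv, images) must be set; "
                f"got {sum(sources)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "times" in syn:
                syn["times"] = tuple(float(t) for t in syn["times"])
            raw["synthetic"] = CohortSpec(**syn)
        if "qc" in raw and raw["qc"] is not None:
            raw["qc"] = tr.QCConfig(**raw["qc"])
        if "model_params" in raw and raw["model_params"] is not None:
            raw["model_params"] = SensorModelParams(**raw["model_params"])
        if "frame_spec" in raw and raw["frame_spec"] is not None:
            fs = dict(raw["frame_spec"])
            for key in ("shape", "cell_radius_range", "nucleus_radius_range"):
                if key in fs:
                    fs[key] = tuple(fs[key])
            raw["frame_spec"] = FrameSpec(**fs)
        if "initial_window" in raw:
            raw["initial_window"] = tuple(raw["initial_window"])
        return cls(**raw)


def segment_movie(
    channels: Mapping[str, np.ndarray],
    times: np.ndarray,
    nucleus_threshold: float | None = None,
    body_threshold: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Segment, track and quantify a multi-channel movie.

    ``channels`` must contain ``nuclear`` and ``sensor`` stacks of shape
    (T, H, W); a ``body`` channel guides the cell contour (nuclei are
    dilated as a fallback when absent).  Returns the tidy trace table and a
    dict of per-frame label maps.
    """
    nuclear = channels["nuclear"]
    nuc_maps, cell_maps, cyt_maps = [], [], []
    for k in range(nuclear.shape[0]):
        nuclei = seg.segment_nuclei(nuclear[k], threshold=nucleus_threshold)
        body = channels["body"][k] if "body" in channels else None
        if body is not None:
            cells = seg.expand_to_cells(nuclei, body, body_threshold=body_threshold)
        else:
            cells = seg.expand_to_cells(nuclei, np.zeros_like(nuclear[k]), body_threshold=np.inf)
        cyto = seg.derive_cytoplasm(cells, nuclei)
        nuc_maps.append(nuclei)
        cell_maps.append(cells)
        cyt_maps.append(cyto)
    tracks = seg.track_nuclei(nuc_maps)
    measurements = seg.quantify(
        tracks, nuc_maps, cyt_maps, channels, times, cell_maps=cell_maps
    )
    trace_table = tr.measurements_to_traces(measurements)
    masks = {"nuclei": nuc_maps, "cells": cell_maps, "cytoplasm": cyt_maps, "tracks": tracks,
             "measurements": measurements}
    return trace_table, masks


def _acquire_traces(config: PipelineConfig, out: Path) -> tuple[pd.DataFrame, dict]:
    """Stage 1: produce the tidy trace table from whichever source is configured."""
    info: dict = {}
    if config.synthetic is not None:
        spec = spec_with(config.synthetic, seed=config.seed)
        truth = generate_cohort(spec)
        info["planted_class_counts"] = truth.cells.cls.value_counts().to_dict()
        if config.render_images:
            stack = render_frames(truth, config.frame_spec, config.model_params)
            trace_table, _ = segment_movie(stack.channels, stack.times)
        else:
            trace_table = simulate_cohort_traces(truth, config.model_params)
            trace_table["full_length"] = True
        truth.cells.to_csv(out / "ground_truth.csv", index=False)
        info["source"] = "synthetic"
        return trace_table, info
    if config.traces_csv is not None:
        trace_table = pd.read_csv(config.traces_csv)
        if not {"cell_id", "time_min", "ratio"} <= set(trace_table.columns):
            raise StageError("input stage: trace CSV needs cell_id, time_min, ratio columns")
        info["source"] = str(config.traces_csv)
        return trace_table, info
    import tifffile

    channels = {name: tifffile.imread(path) for name, path in config.images.items()}
    nt = next(iter(channels.values())).shape[0]
    times = np.arange(nt, dtype=float) * config.frame_interval_min
    trace_table, _ = segment_movie(channels, times)
    info["source"] = "images"
    return trace_table, info


def _resolve_theta(config: PipelineConfig, out: Path) -> tuple[float, dict]:
    if isinstance(config.theta, (int, float)):
        return float(config.theta), {"theta_mode": "fixed"}
    if config.theta != "auto":
        raise ConfigError(f"theta must be a number or 'auto', got {config.theta!r}")
    if config.control_csv is None:
        raise ConfigError("theta='auto' requires control_csv with control-cell traces")
    control = pd.read_csv(config.control_csv)
    stim = config.stim_time if config.stim_time is not None else 0.0
    feats = tr.compute_features(control, stim, config.initial_window)
    theta = tr.derive_threshold(feats.final_response)
    feats.to_csv(out / "control_features.csv", index=False)
    return theta, {
        "theta_mode": "control-derived",
        "control_n": int(len(feats)),
        "control_fr_mean": float(feats.final_response.mean()),
    }


def _infer_activity(
    config: PipelineConfig, summary: pd.DataFrame, out: Path, stim_time: float
) -> dict:
    """Stage 5: invert the population-median trace into kinase activity.

    The median measured ratio is rescaled so its basal level matches the
    model's steady-state ratio at the assumed baseline activity; activity is
    then obtained both per-timepoint (steady-state calibration inversion)
    and by fitting a parametric activity profile to the whole time course.
    """
    params = config.model_params
    t = summary.time_min.to_numpy(dtype=float)
    median = summary["median"].to_numpy(dtype=float)
    basal = tr.basal_level(median)
    model_basal = steady_state_ratio(params, config.baseline_activity)
    scaled = median * (model_basal / basal)
    curve = build_calibration(params)
    steady_activity = infer_activity_steady(scaled, curve)
    fit = fit_activity_timecourse(t, scaled, params, t_on=stim_time)
    fitted_ratio = simulate_relocation(params, fit.profile, t)
    table = pd.DataFrame(
        {
            "time_min": t,
            "median_ratio": median,
            "model_scale_ratio": scaled,
            "fitted_ratio": fitted_ratio,
            "activity_steady_state": steady_activity,
            "activity_fitted": fit.profile(t),
        }
    )
    table.to_csv(out / "activity.csv", index=False)
    prof = fit.profile
    return {
        "fitted_a0": prof.a0,
        "fitted_amax": prof.amax,
        "fitted_tau_rise": prof.tau_rise,
        "fit_residual_norm": fit.residual_norm,
        "fit_converged": fit.converged,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return a machine-readable report.

    Writes ``traces.csv``, ``qc_log.csv``, ``features.csv``,
    ``summary.csv``, ``ordering.csv``, ``activity.csv`` (and
    ``quadrants.csv`` when a marker is present) under ``config.out_dir``,
    plus the report itself as ``report.json``.  Stage failures re-raise as
    :class:`StageError` naming the stage and the cell count at failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    stim = config.stim_time
    if stim is None and config.synthetic is not None:
        stim = config.synthetic.stim_time
    stim = 0.0 if stim is None else float(stim)

    trace_table, info = _acquire_traces(config, out)
    report.update(info)
    report["cells_in"] = int(trace_table.cell_id.nunique())
    trace_table.to_csv(out / "traces.csv", index=False)

    kept, qc_log = tr.qc_filter(trace_table, config.qc)
    qc_log.to_csv(out / "qc_log.csv", index=False)
    report["cells_after_qc"] = int(kept.cell_id.nunique())
    report["qc_rejections"] = {
        reason: int(n) for reason, n in qc_log.reason.value_counts().items()
    }
    if kept.empty:
        raise StageError(f"qc stage: no cells left of {report['cells_in']}")

    try:
        theta, theta_info = _resolve_theta(config, out)
        report.update(theta_info)
        report["theta"] = theta
        feats = tr.compute_features(kept, stim, config.initial_window)
        feats = tr.classify_table(feats, theta, config.slow_factor)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise StageError(f"feature stage failed with {report['cells_after_qc']} cells: {exc}") from exc
    feats.to_csv(out / "features.csv", index=False)
    report["class_counts"] = {
        cls: int((feats.cls == cls).sum()) for cls in tr.CLASS_ORDER
    }

    kept = kept.copy()
    kept["normalized"] = kept.groupby("cell_id").ratio.transform(lambda r: r / r.iloc[:3].mean())
    summary = tr.population_summary(kept, value="ratio")
    summary_norm = tr.population_summary(kept, value="normalized")
    summary["median_normalized"] = summary_norm["median"]
    summary["p25_normalized"] = summary_norm["p25"]
    summary["p75_normalized"] = summary_norm["p75"]
    summary.to_csv(out / "summary.csv", index=False)

    ordered, boundaries = tr.sort_for_heatmap(feats)
    ordered.to_csv(out / "ordering.csv", index=False)
    report["heatmap_class_offsets"] = boundaries

    if feats.marker_enrichment.notna().any():
        quads, counts, mean_traces = tr.marker_quadrants(
            feats, theta, config.marker_threshold, traces=kept
        )
        quads.to_csv(out / "quadrants.csv", index=False)
        if mean_traces is not None:
            mean_traces.to_csv(out / "quadrant_mean_traces.csv", index=False)
        report["quadrant_counts"] = {
            rec.quadrant: int(rec.n_cells) for rec in counts.itertuples()
        }

    try:
        report["activity"] = _infer_activity(config, summary, out, stim)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"activity stage failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
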