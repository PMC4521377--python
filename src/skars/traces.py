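"""Single-cell statistics for relocation-sensor traces.

A *trace* is the nuclear-to-cytoplasmic sensor ratio of one tracked cell
over time (unitless).  Per cell the analysis computes the basal level B
(mean of the first three pre-stimulus ratios), the normalized trace R(t)/B,
the initial response IR (one minus the mean of three normalized points
3-5 min after the stimulus), the final response FR (one minus the mean of
the last three normalized points), and a responder class:

* ``non_responding`` — FR below the threshold θ;
* ``slow``           — FR > 1.5 x IR (the response builds up late);
* ``responding``     — everything else.

θ is either fixed (0.2 for cell-wall-stress experiments) or derived as a
percentile of the final responses of a signalling-dead / non-docking
control population.  The module also provides trace quality control,
population median/quartile summaries, heat-map ordering, and the
cell-cycle-marker quadrant analysis (marker enrichment E = nuclear minus
cytoplasmic marker intensity before the stimulus).

Tabular contract: tidy DataFrames with one row per cell per timepoint,
columns ``cell_id``, ``time_min``, ``ratio`` and optionally intensity,
marker and QC columns (as produced by :mod:`skars.synth` and
:func:`skars.segment.quantify` via :func:`measurements_to_traces`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = [
    "QCConfig",
    "InsufficientDataError",
    "measurements_to_traces",
    "qc_filter",
    "basal_level",
    "normalize_trace",
    "response_features",
    "compute_features",
    "derive_threshold",
    "classify",
    "classify_table",
    "population_summary",
    "sort_for_heatmap",
    "marker_quadrants",
]

CLASS_ORDER = ("responding", "slow", "non_responding")


class InsufficientDataError(ValueError):
    """A trace lacks the points required by a formula (window named in the message)."""


def measurements_to_traces(
    measurements: pd.DataFrame,
    sensor_channel: str = "sensor",
    nuclear_channel: str = "nuclear",
    marker_channel: str | None = "cycle",
) -> pd.DataFrame:
    """Convert a segmentation measurement table into the tidy trace format.

    The sensor ratio is mean nuclear over mean cytoplasmic intensity; rows
    flagged ``empty_cytoplasm`` get an undefined (NaN) ratio.  QC columns
    (areas, nuclear-marker intensity, sensor cell intensity, full_length)
    are carried through when present.
    """
    df = measurements.copy()
    nuc = df[f"nuc_{sensor_channel}"]
    cyt = df[f"cyt_{sensor_channel}"]
    out = pd.DataFrame(
        {
            "cell_id": df.cell_id,
            "time_min": df.time_min,
            "nuclear": nuc,
            "cytoplasmic": cyt,
            "ratio": nuc / cyt,
        }
    )
    if "empty_cytoplasm" in df:
        out.loc[df.empty_cytoplasm.astype(bool).to_numpy(), "ratio"] = np.nan
    for src, dst in [
        ("nucleus_area", "nucleus_area"),
        ("cell_area", "cell_area"),
        (f"nuc_{nuclear_channel}", "nuclear_marker"),
        ("full_length", "full_length"),
    ]:
        if src in df:
            out[dst] = df[src]
    if f"nuc_{sensor_channel}" in df and f"cyt_{sensor_channel}" in df:
        # cell-level sensor fluorescence, area-weighted when areas are known
        if "nucleus_area" in df and "cell_area" in df:
            na, ca = df.nucleus_area, df.cell_area
            out["sensor_cell"] = (nuc * na + cyt * (ca - na).clip(lower=0)) / ca
        else:
            out["sensor_cell"] = (nuc + cyt) / 2.0
    if marker_channel is not None and f"nuc_{marker_channel}" in df:
        out["marker_nuclear"] = df[f"nuc_{marker_channel}"]
        out["marker_cytoplasmic"] = df[f"cyt_{marker_channel}"]
    return out


@dataclass(frozen=True)
class QCConfig:
    """Trace quality-control bounds.

    A trace passes when it spans the whole movie (if required) and the
    coefficient of variation (sd/mean) of each available stability feature
    — nucleus area, cell area, nuclear-marker fluorescence, sensor cell
    fluorescence — stays at or below its bound.  Criteria whose feature
    column is absent are skipped.
    """

    max_cv_nucleus_area: float = 0.2
    max_cv_cell_area: float = 0.2
    max_cv_nuclear_marker: float = 0.2
    max_cv_sensor_cell: float = 0.2
    require_full_length: bool = True

    def __post_init__(self) -> None:
        for name in ("max_cv_nucleus_area", "max_cv_cell_area",
                     "max_cv_nuclear_marker", "max_cv_sensor_cell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


_QC_CRITERIA = (
    ("nucleus_area", "max_cv_nucleus_area", "nucleus area variability"),
    ("cell_area", "max_cv_cell_area", "cell area variability"),
    ("nuclear_marker", "max_cv_nuclear_marker", "nuclear marker fluorescence variability"),
    ("sensor_cell", "max_cv_sensor_cell", "sensor cell fluorescence variability"),
)


def _cv(values: np.ndarray) -> float:
    mean = np.nanmean(values)
    if mean == 0:
        return 0.0 if np.nanstd(values) == 0 else np.inf
    return float(np.nanstd(values) / abs(mean))


def qc_filter(
    traces: pd.DataFrame, qc: QCConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply per-trace quality control; return (kept traces, rejection log).

    The log has one row per rejected cell with the first failing criterion
    (``not full length``, ``undefined ratio``, or the CV bound that failed,
    with the measured CV).
    """
    qc = qc or QCConfig()
    rejections = []
    kept_ids = []
    for cell_id, group in traces.groupby("cell_id", sort=True):
        reason = None
        cv_value = np.nan
        if qc.require_full_length and "full_length" in group and not group.full_length.all():
            reason = "not full length"
        elif group.ratio.isna().any():
            reason = "undefined ratio"
        else:
            for column, bound_name, label in _QC_CRITERIA:
                if column not in group:
                    continue
                cv = _cv(group[column].to_numpy(dtype=float))
                if cv > getattr(qc, bound_name):
                    reason, cv_value = label, cv
                    break
        if reason is None:
            kept_ids.append(cell_id)
        else:
            rejections.append({"cell_id": cell_id, "reason": reason, "cv": cv_value})
    kept = traces[traces.cell_id.isin(kept_ids)].copy()
    log = pd.DataFrame(rejections, columns=["cell_id", "reason", "cv"])
    return kept, log


def basal_level(ratios: Sequence[float]) -> float:
    """Basal level B: the arithmetic mean of the first three ratio values."""
    r = np.asarray(ratios, dtype=float)
    if r.size < 3:
        raise InsufficientDataError(
            f"basal level needs >= 3 pre-stimulus points, got {r.size}"
        )
    return float(r[:3].mean())


def normalize_trace(ratios: Sequence[float]) -> np.ndarray:
    """Trace divided by its basal level."""
    r = np.asarray(ratios, dtype=float)
    return r / basal_level(r)


def _initial_window_indices(
    times: np.ndarray, stim_time: float, window: tuple[float, float]
) -> np.ndarray:
    """Indices of the 3 points nearest the post-stimulus window [w0, w1]."""
    rel = times - stim_time
    post = np.flatnonzero(rel > 0)
    if post.size < 3:
        raise InsufficientDataError(
            f"initial-response window {window}: need >= 3 post-stimulus points, got {post.size}"
        )
    lo, hi = window
    dist = np.where(
        (rel[post] >= lo) & (rel[post] <= hi),
        0.0,
        np.minimum(np.abs(rel[post] - lo), np.abs(rel[post] - hi)),
    )
    # equal distance prefers the later timepoint: under sparse sampling the
    # response has typically plateaued there, while the earlier candidate
    # still reflects pre-response lag
    order = np.lexsort((-rel[post], dist))
    pick = post[order[:3]]
    return np.sort(pick)


def response_features(
    times: Sequence[float],
    ratios: Sequence[float],
    stim_time: float = 0.0,
    initial_window: tuple[float, float] = (3.0, 5.0),
) -> tuple[float, float]:
    """Initial and final response of one trace.

    FR = 1 - mean of the last three normalized ratios; IR = 1 - mean of the
    three normalized ratios nearest to ``initial_window`` minutes after the
    stimulus.  Both are unitless; positive values mean nuclear exit.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if t.size != r.size:
        raise ValueError("times and ratios must have the same length")
    if t.size < 3:
        raise InsufficientDataError("final-response window: need >= 3 points")
    norm = normalize_trace(r)
    fr = 1.0 - float(norm[-3:].mean())
    idx = _initial_window_indices(t, stim_time, initial_window)
    ir = 1.0 - float(norm[idx].mean())
    return ir, fr


def derive_threshold(control_fr: Sequence[float], q: float = 95.0) -> float:
    """Responder threshold θ from a non-docking / signalling-dead control.

    θ is the q-th percentile (default 95) of the control population's final
    responses, so ~(100-q)% of genuinely unresponsive cells fall above it.
    """
    fr = np.asarray(control_fr, dtype=float)
    fr = fr[np.isfinite(fr)]
    if fr.size < 20:
        raise InsufficientDataError(
            f"threshold derivation needs >= 20 control cells, got {fr.size}; "
            "use the fixed-threshold mode instead"
        )
    return float(np.percentile(fr, q))


def classify(ir: float, fr: float, theta: float, slow_factor: float = 1.5) -> str:
    """Responder class from (IR, FR).

    FR < θ → ``non_responding``; otherwise ``slow`` when FR exceeds
    ``slow_factor`` x IR (strictly), else ``responding``.  Boundaries
    (FR = θ, FR = slow_factor·IR) classify as responding.
    """
    if not (np.isfinite(ir) and np.isfinite(fr)):
        raise ValueError("features must be finite")
    if fr < theta:
        return "non_responding"
    if fr > slow_factor * ir:
        return "slow"
    return "responding"


def compute_features(
    traces: pd.DataFrame,
    stim_time: float = 0.0,
    initial_window: tuple[float, float] = (3.0, 5.0),
) -> pd.DataFrame:
    """Per-cell feature table: basal level, IR, FR and marker enrichment.

    Marker enrichment E is the pre-stimulus mean of nuclear minus
    cytoplasmic marker intensity (NaN when no marker columns are present).
    """
    rows = []
    for cell_id, group in traces.groupby("cell_id", sort=True):
        group = group.sort_values("time_min")
        t = group.time_min.to_numpy(dtype=float)
        r = group.ratio.to_numpy(dtype=float)
        b = basal_level(r)
        ir, fr = response_features(t, r, stim_time, initial_window)
        row = {"cell_id": cell_id, "basal": b, "initial_response": ir, "final_response": fr}
        if "marker_nuclear" in group:
            pre = t < stim_time if np.any(t < stim_time) else slice(None)
            enrich = (group.marker_nuclear - group.marker_cytoplasmic).to_numpy(dtype=float)
            row["marker_enrichment"] = float(np.mean(enrich[pre]))
        else:
            row["marker_enrichment"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def classify_table(
    features: pd.DataFrame, theta: float, slow_factor: float = 1.5
) -> pd.DataFrame:
    """Add a ``cls`` column to a feature table."""
    out = features.copy()
    out["cls"] = [
        classify(ir, fr, theta, slow_factor)
        for ir, fr in zip(out.initial_response, out.final_response)
    ]
    return out


def population_summary(traces: pd.DataFrame, value: str = "ratio") -> pd.DataFrame:
    """Per-timepoint median and quartiles of the population.

    All cells must share one time grid (the movie's frame times); otherwise
    an alignment error is raised.  Percentiles use linear interpolation
    between order statistics.  Returns columns ``time_min``, ``median``,
    ``p25``, ``p75``.
    """
    grids = {tuple(g.sort_values("time_min").time_min) for _, g in traces.groupby("cell_id")}
    if len(grids) != 1:
        raise ValueError(f"traces are on {len(grids)} different time grids; align them first")
    pivot = traces.pivot_table(index="time_min", columns="cell_id", values=value)
    data = pivot.to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "time_min": pivot.index.to_numpy(dtype=float),
            "median": np.percentile(data, 50, axis=1),
            "p25": np.percentile(data, 25, axis=1),
            "p75": np.percentile(data, 75, axis=1),
        }
    )


def sort_for_heatmap(features: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Heat-map ordering: class blocks, descending final response within each.

    Cells are grouped responding / slow / non_responding (requires a ``cls``
    column) and sorted by descending FR inside each block, ties broken by
    ascending cell id.  Returns the reordered feature table (with the basal
    level kept as the side annotation) and the start row of each class
    block.
    """
    if "cls" not in features:
        raise ValueError("features must carry a 'cls' column; run classify_table first")
    blocks = []
    boundaries: dict[str, int] = {}
    offset = 0
    for cls in CLASS_ORDER:
        block = features[features.cls == cls].sort_values(
            ["final_response", "cell_id"], ascending=[False, True], kind="stable"
        )
        boundaries[cls] = offset
        offset += len(block)
        blocks.append(block)
    ordered = pd.concat(blocks, ignore_index=True)
    return ordered, boundaries


def marker_quadrants(
    features: pd.DataFrame,
    theta: float,
    tau_m: float | str = 0.0,
    traces: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Quadrant analysis of marker enrichment vs final response.

    Each cell is marker-positive when its pre-stimulus enrichment E is
    strictly above ``tau_m`` (pass ``"otsu"`` to derive the cutoff from the
    E distribution) and responding when FR >= θ.  Returns the feature table
    with ``marker_state`` and ``quadrant`` columns, a per-quadrant count
    table, and — when the tidy traces are supplied — the mean normalized
    trace of each quadrant.
    """
    feats = features.copy()
    e = feats.marker_enrichment.to_numpy(dtype=float)
    if np.isnan(e).all():
        raise ValueError("no marker enrichment available (missing pre-stimulus marker frames)")
    if isinstance(tau_m, str):
        if tau_m != "otsu":
            raise ValueError(f"unknown marker threshold mode {tau_m!r}")
        tau_m = float(threshold_otsu(e[np.isfinite(e)]))
    positive = e > tau_m
    responding = feats.final_response.to_numpy(dtype=float) >= theta
    feats["marker_state"] = np.where(positive, "nuclear", "cytoplasmic")
    names = {
        (True, True): "marker+/responding",
        (True, False): "marker+/non_responding",
        (False, True): "marker-/responding",
        (False, False): "marker-/non_responding",
    }
    feats["quadrant"] = [names[(bool(p), bool(r))] for p, r in zip(positive, responding)]
    counts = (
        feats.groupby("quadrant").size().rename("n_cells").reset_index()
    )
    mean_traces = None
    if traces is not None:
        merged = traces.merge(feats[["cell_id", "quadrant"]], on="cell_id")
        merged["normalized"] = merged.groupby("cell_id").ratio.transform(
            lambda r: r / r.iloc[:3].mean()
        )
        mean_traces = (
            merged.groupby(["quadrant", "time_min"]).normalized.mean().reset_index()
        )
    return feats, counts, mean_traces
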