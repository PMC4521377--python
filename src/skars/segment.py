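"""Image quantification for relocation-sensor movies.

Nuclei are segmented by thresholding the nuclear-marker channel, the cell
around each nucleus is recovered by seeded region growing over a cell-body
mask, and the cytoplasm ring is the cell minus the nucleus expanded by two
pixels.  Nuclei are tracked across frames by nearest-centroid assignment,
and mean nuclear/cytoplasmic intensities are extracted per channel to feed
the trace analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import dilation, disk
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = [
    "segment_nuclei",
    "expand_to_cells",
    "derive_cytoplasm",
    "track_nuclei",
    "quantify",
    "relabel_to_tracks",
    "iou",
]


def segment_nuclei(
    image: np.ndarray,
    threshold: float | None = None,
    min_area: int = 20,
    max_area: int = 2000,
) -> np.ndarray:
    """Segment nuclei by thresholding a nuclear-marker frame.

    Pixels above the threshold (Otsu by default; pass ``threshold`` for a
    fixed value) are grouped into 8-connected components and filtered by
    area.  A constant image yields an empty label map, not an error.
    Labels are renumbered to 1..n.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D frame, got shape {img.shape}")
    if threshold is None:
        if np.ptp(img) == 0:
            return np.zeros(img.shape, dtype=np.int32)
        threshold = threshold_otsu(img)
    mask = img > threshold
    labels = cc_label(mask, connectivity=2)
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 1
    for region in regionprops(labels):
        if min_area <= region.area <= max_area:
            out[labels == region.label] = nxt
            nxt += 1
    return out


def expand_to_cells(
    nuclei: np.ndarray,
    body_image: np.ndarray,
    body_threshold: float | None = None,
    fallback_radius: int = 8,
) -> np.ndarray:
    """Grow one cell region per nucleus over the cell-body mask.

    The body channel is thresholded (Otsu by default) into a foreground
    mask; cells are obtained by watershed region growing seeded at the
    nuclei, so regions are disjoint and each contains its nucleus.  A
    nucleus whose pixels fall outside the body mask gets a fallback disk
    (nucleus dilated by ``fallback_radius``) clipped against other cells,
    and a warning is logged.
    """
    nuclei = np.asarray(nuclei)
    body = np.asarray(body_image, dtype=float)
    if nuclei.shape != body.shape:
        raise ValueError("nuclei and body images must have the same shape")
    if body_threshold is None:
        body_threshold = threshold_otsu(body) if np.ptp(body) > 0 else np.inf
    mask = body > body_threshold
    # every nucleus pixel belongs to its cell even if the body mask misses it
    mask |= nuclei > 0
    cells = watershed(np.zeros_like(body), markers=nuclei, mask=mask)
    for lab in np.unique(nuclei):
        if lab == 0:
            continue
        nucleus = nuclei == lab
        cell = cells == lab
        if cell.sum() <= nucleus.sum():
            logger.warning(
                "nucleus %d has no surrounding cell-body signal; using a fallback disk", lab
            )
            fallback = dilation(nucleus, disk(fallback_radius))
            cells[fallback & (cells == 0)] = lab
    return cells.astype(np.int32)


def derive_cytoplasm(
    cells: np.ndarray, nuclei: np.ndarray, expand_px: int = 2
) -> np.ndarray:
    """Cytoplasm ring: the cell minus its nucleus dilated by ``expand_px``.

    The dilation uses a disk structuring element of radius ``expand_px``
    (``expand_px=0`` subtracts the nucleus exactly).  Cells whose ring comes
    out empty are flagged with a warning; their label is simply absent from
    the result.  Label ids must match between the two maps.
    """
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    if cells.shape != nuclei.shape:
        raise ValueError("cell and nucleus label maps must have the same shape")
    nuc_ids = set(np.unique(nuclei)) - {0}
    cell_ids = set(np.unique(cells)) - {0}
    if not nuc_ids <= cell_ids:
        raise ValueError(
            f"nucleus labels {sorted(nuc_ids - cell_ids)} have no matching cell label"
        )
    selem = disk(expand_px) if expand_px > 0 else None
    cyto = np.zeros_like(cells, dtype=np.int32)
    for lab in sorted(cell_ids):
        nucleus = nuclei == lab
        grown = dilation(nucleus, selem) if selem is not None else nucleus
        ring = (cells == lab) & ~grown
        if not ring.any():
            logger.warning("cell %d has an empty cytoplasm ring; flagged", lab)
            continue
        cyto[ring] = lab
    return cyto


def _centroids(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    regions = regionprops(labels)
    cents = np.array([r.centroid for r in regions]).reshape(-1, 2)
    labs = np.array([r.label for r in regions], dtype=int)
    return cents, labs


def track_nuclei(label_maps: Sequence[np.ndarray], max_displacement: float = 10.0) -> pd.DataFrame:
    """Track nuclei across frames by greedy nearest-centroid assignment.

    Pairs are matched in ascending-distance order (ties broken by lower
    label id) subject to the displacement gate; unmatched objects start new
    tracks.  Returns a table with columns ``track_id``, ``frame``,
    ``label``, ``y``, ``x`` plus a boolean ``full_length`` marking tracks
    present in every frame — downstream analysis keeps only those.
    """
    if len(label_maps) == 0:
        raise ValueError("need at least one frame")
    rows: list[dict] = []
    next_track = 0
    prev: dict[int, tuple[float, float]] = {}  # track_id -> last centroid
    for frame_idx, labels in enumerate(label_maps):
        cents, labs = _centroids(np.asarray(labels))
        assigned: dict[int, int] = {}  # label -> track
        if prev and labs.size:
            track_ids = list(prev)
            prev_pts = np.array([prev[t] for t in track_ids])
            dists = cdist(prev_pts, cents)
            order = sorted(
                ((dists[i, j], track_ids[i], int(labs[j]), j)
                 for i in range(len(track_ids)) for j in range(labs.size)),
                key=lambda r: (r[0], r[2]),
            )
            used_tracks: set[int] = set()
            for d, tid, lab, j in order:
                if d > max_displacement or tid in used_tracks or lab in assigned:
                    continue
                assigned[lab] = tid
                used_tracks.add(tid)
                prev[tid] = tuple(cents[j])
        for j, lab in enumerate(labs):
            lab = int(lab)
            if lab not in assigned:
                assigned[lab] = next_track
                prev[next_track] = tuple(cents[j])
                next_track += 1
            rows.append(
                {
                    "track_id": assigned[lab],
                    "frame": frame_idx,
                    "label": lab,
                    "y": cents[j][0],
                    "x": cents[j][1],
                }
            )
    table = pd.DataFrame(rows, columns=["track_id", "frame", "label", "y", "x"])
    n_frames = len(label_maps)
    counts = table.groupby("track_id")["frame"].nunique()
    table["full_length"] = table.track_id.map(counts == n_frames)
    return table


def quantify(
    tracks: pd.DataFrame,
    nucleus_maps: Sequence[np.ndarray],
    cytoplasm_maps: Sequence[np.ndarray],
    channel_frames: Mapping[str, Sequence[np.ndarray]],
    times: Sequence[float],
    cell_maps: Sequence[np.ndarray] | None = None,
    background: str | None = "median-outside",
) -> pd.DataFrame:
    """Per-cell, per-frame mean intensities over nucleus and cytoplasm masks.

    For each requested channel the mean over the nucleus and the cytoplasm
    ring is reported (columns ``nuc_<channel>``, ``cyt_<channel>``); with
    ``background="median-outside"`` the per-frame median intensity outside
    every cell is subtracted first (camera-offset correction).  Rows with an
    empty cytoplasm are emitted with ``empty_cytoplasm=True`` and NaN
    cytoplasmic means — the ratio is undefined there.  Nucleus and cell
    areas are included for downstream quality control.
    """
    times = np.asarray(times, dtype=float)
    if len(nucleus_maps) != times.size:
        raise ValueError("times must match the number of frames")
    rows = []
    for frame_idx, t in enumerate(times):
        nuc = np.asarray(nucleus_maps[frame_idx])
        cyt = np.asarray(cytoplasm_maps[frame_idx])
        cell = np.asarray(cell_maps[frame_idx]) if cell_maps is not None else None
        imgs = {}
        for name, frames in channel_frames.items():
            img = np.asarray(frames[frame_idx], dtype=float)
            if background == "median-outside":
                outside = (nuc == 0) & (cyt == 0) if cell is None else (cell == 0)
                img = img - (np.median(img[outside]) if outside.any() else 0.0)
            imgs[name] = img
        sub = tracks[tracks.frame == frame_idx]
        for rec in sub.itertuples():
            nmask = nuc == rec.label
            cmask = cyt == rec.label
            row = {
                "cell_id": int(rec.track_id),
                "frame": frame_idx,
                "time_min": float(t),
                "nucleus_area": int(nmask.sum()),
                "cell_area": int(nmask.sum() + cmask.sum())
                if cell is None
                else int((cell == rec.label).sum()),
                "empty_cytoplasm": not cmask.any(),
                "full_length": bool(rec.full_length),
            }
            for name, img in imgs.items():
                row[f"nuc_{name}"] = float(img[nmask].mean()) if nmask.any() else np.nan
                row[f"cyt_{name}"] = float(img[cmask].mean()) if cmask.any() else np.nan
            rows.append(row)
    return pd.DataFrame(rows).sort_values(["cell_id", "frame"]).reset_index(drop=True)


def relabel_to_tracks(tracks: pd.DataFrame, label_maps: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Rewrite per-frame labels so every object carries its track id + 1."""
    out = []
    for frame_idx, labels in enumerate(label_maps):
        labels = np.asarray(labels)
        new = np.zeros_like(labels, dtype=np.int32)
        for rec in tracks[tracks.frame == frame_idx].itertuples():
            new[labels == rec.label] = rec.track_id + 1
        out.append(new)
    return out


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks (1.0 for two empties)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
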