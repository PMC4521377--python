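"""Ground-truthed synthetic cohorts of relocation-sensor cells.

Generates single-cell ratio traces and multi-channel time-lapse image
stacks with the statistical structure the downstream analysis assumes:

* a responder-class mixture (responding / slow-responding / non-responding,
  default fractions 0.72 / 0.11 / 0.17),
* log-normal heterogeneity of basal nuclear enrichment (median ~3-fold),
* relocation kinetics on the minutes scale driven by the compartment model,
* a binary cell-cycle-marker state per cell (nuclear vs cytoplasmic),
* additive measurement noise on the ratio and per-pixel image noise.

Everything is reproducible from ``(spec, seed)``: each cell draws from its
own seeded random stream, so traces do not depend on generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from skars.model import ActivityProfile, SensorModelParams, simulate_relocation, steady_state_ratio

__all__ = [
    "CLASSES",
    "CohortSpec",
    "CohortGroundTruth",
    "FrameSpec",
    "ImageStack",
    "SingleCellTrace",
    "GeometryError",
    "generate_cohort",
    "simulate_cell_trace",
    "simulate_cohort_traces",
    "render_frames",
]

CLASSES = ("responding", "slow", "non_responding")


class GeometryError(RuntimeError):
    """Cells could not be placed without overlap; use fewer or smaller cells."""


@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of a synthetic cohort.

    Class fractions default to the mixture observed for pheromone-stimulated
    cells (72 % responding, 11 % slow, 17 % non-responding).  Basal nuclear
    enrichment is log-normal with median 3 and log-sd 0.5 (interquartile
    range ~2.1-4.2).  The kinase-activity baseline is 0.2 (unstimulated
    activity), rising to 1 in responders.  Non-responders show a transient
    activation that returns to baseline within minutes.
    """

    n_cells: int = 300
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"responding": 0.72, "slow": 0.11, "non_responding": 0.17}
    )
    basal_median: float = 3.0
    basal_log_sd: float = 0.5
    tau_jitter_log_sd: float = 0.15
    marker_p_nuclear: Mapping[str, float] = field(
        default_factory=lambda: {"responding": 0.7, "slow": 0.3, "non_responding": 0.2}
    )
    ratio_noise_sd: float = 0.05
    intensity_noise_sd: float = 2.0
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 36))
    stim_time: float = 5.0
    a0: float = 0.2
    amax: float = 1.0
    tau_rise_responding: float = 1.0
    tau_rise_slow: float = 8.0
    slow_onset_delay: float = 5.0
    transient_amplitude: float = 0.5
    transient_decay: float = 2.0
    cyto_intensity_median: float = 200.0
    cyto_intensity_log_sd: float = 0.2
    marker_contrast: float = 200.0
    marker_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        fr = dict(self.class_fractions)
        if set(fr) != set(CLASSES):
            raise ValueError(f"class_fractions must have keys {CLASSES}, got {sorted(fr)}")
        total = sum(fr.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("class fractions must be non-negative")
        t = np.asarray(self.times)
        if t.size < 6 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing with at least 6 points")

    def profile_for(self, cls: str, tau_scale: float = 1.0) -> ActivityProfile:
        """Planted activity profile for a responder class.

        responding: fast rise to the plateau at the stimulus; slow: the same
        plateau but delayed onset and a slow rise, so the initial response
        trails the final one; non_responding: a transient burst that decays
        back to the baseline (an early sensor exit followed by recovery).
        """
        if cls == "responding":
            return ActivityProfile(
                a0=self.a0, amax=self.amax, t_on=self.stim_time,
                tau_rise=self.tau_rise_responding * tau_scale,
            )
        if cls == "slow":
            return ActivityProfile(
                a0=self.a0, amax=self.amax, t_on=self.stim_time + self.slow_onset_delay,
                tau_rise=self.tau_rise_slow * tau_scale,
            )
        if cls == "non_responding":
            return ActivityProfile(
                a0=self.a0, amax=min(1.0, self.a0 + self.transient_amplitude),
                t_on=self.stim_time, tau_rise=self.tau_rise_responding * tau_scale,
                tau_decay=self.transient_decay,
            )
        raise ValueError(f"unknown class {cls!r}")


@dataclass
class CohortGroundTruth:
    """Planted per-cell parameters of a synthetic cohort.

    ``cells`` has one row per cell: cell_id, cls, basal_ratio, tau_scale,
    a0, amax, t_on, tau_rise, tau_decay, marker_nuclear, cyto_intensity;
    rendering adds x, y, cell_radius, nucleus_radius.
    """

    spec: CohortSpec
    seed: int
    cells: pd.DataFrame

    def profile_for_cell(self, cell_id: int) -> ActivityProfile:
        row = self.cells.loc[self.cells.cell_id == cell_id].iloc[0]
        decay = row.tau_decay if np.isfinite(row.tau_decay) else None
        return ActivityProfile(
            a0=row.a0, amax=row.amax, t_on=row.t_on, tau_rise=row.tau_rise, tau_decay=decay
        )


def _cell_rng(seed: int, cell_id: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, cell_id, stream])


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> CohortGroundTruth:
    """Draw a ground-truthed cohort from a :class:`CohortSpec`.

    Class labels are multinomial with the spec's fractions; basal ratios and
    per-cell rise-timescale jitter are log-normal; the marker state is
    Bernoulli with a class-dependent probability.  Deterministic for fixed
    ``(spec, seed)`` (``seed`` defaults to ``spec.seed``).
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng([seed, 0xC0F])
    probs = [spec.class_fractions[c] for c in CLASSES]
    labels = rng.choice(len(CLASSES), size=spec.n_cells, p=probs)
    rows = []
    for cid, li in enumerate(labels):
        cls = CLASSES[li]
        crng = _cell_rng(seed, cid)
        basal = spec.basal_median * math.exp(crng.normal(0.0, spec.basal_log_sd))
        tau_scale = math.exp(crng.normal(0.0, spec.tau_jitter_log_sd))
        marker_nuclear = bool(crng.random() < spec.marker_p_nuclear[cls])
        cyto = spec.cyto_intensity_median * math.exp(
            crng.normal(0.0, spec.cyto_intensity_log_sd)
        )
        prof = spec.profile_for(cls, tau_scale)
        rows.append(
            {
                "cell_id": cid,
                "cls": cls,
                "basal_ratio": basal,
                "tau_scale": tau_scale,
                "a0": prof.a0,
                "amax": prof.amax,
                "t_on": prof.t_on,
                "tau_rise": prof.tau_rise,
                "tau_decay": prof.tau_decay if prof.tau_decay is not None else np.nan,
                "marker_nuclear": marker_nuclear,
                "cyto_intensity": cyto,
            }
        )
    return CohortGroundTruth(spec=spec, seed=seed, cells=pd.DataFrame(rows))


@dataclass
class SingleCellTrace:
    """Time-stamped intensities and nuclear:cytoplasmic ratio for one cell."""

    cell_id: int
    times: np.ndarray
    nuclear: np.ndarray
    cytoplasmic: np.ndarray
    ratio: np.ndarray
    marker_nuclear_int: np.ndarray | None = None
    marker_cytoplasmic_int: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "cell_id": self.cell_id,
            "time_min": self.times,
            "nuclear": self.nuclear,
            "cytoplasmic": self.cytoplasmic,
            "ratio": self.ratio,
        }
        if self.marker_nuclear_int is not None:
            d["marker_nuclear"] = self.marker_nuclear_int
            d["marker_cytoplasmic"] = self.marker_cytoplasmic_int
        return pd.DataFrame(d)


def planted_ratio_trace(
    truth: CohortGroundTruth,
    cell_id: int,
    params: SensorModelParams,
    times: Sequence[float] | None = None,
) -> np.ndarray:
    """Noise-free planted ratio: model output rescaled to the cell's basal ratio."""
    spec = truth.spec
    t = np.asarray(spec.times if times is None else times, dtype=float)
    row = truth.cells.loc[truth.cells.cell_id == cell_id].iloc[0]
    prof = truth.profile_for_cell(cell_id)
    model_ratio = simulate_relocation(params, prof, t)
    model_basal = steady_state_ratio(params, prof.a0)
    return model_ratio * (row.basal_ratio / model_basal)


def simulate_cell_trace(
    truth: CohortGroundTruth,
    cell_id: int,
    params: SensorModelParams | None = None,
    noise_sd: float | None = None,
) -> SingleCellTrace:
    """Simulate one cell's measured trace from its planted ground truth.

    The measured ratio is the planted (model-derived, basal-rescaled) ratio
    plus additive Gaussian noise; nuclear intensity is defined as
    ratio x cytoplasmic intensity so the intensity pair is exactly
    consistent with the emitted ratio.  Marker channels carry the planted
    binary state as a nuclear-minus-cytoplasmic intensity contrast.
    """
    spec = truth.spec
    params = params or SensorModelParams()
    if noise_sd is None:
        noise_sd = spec.ratio_noise_sd
    t = np.asarray(spec.times, dtype=float)
    row = truth.cells.loc[truth.cells.cell_id == cell_id].iloc[0]
    rng = _cell_rng(truth.seed, cell_id, stream=1)
    ratio = planted_ratio_trace(truth, cell_id, params)
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, size=t.size)
    ratio = np.maximum(ratio, 1e-6)
    cyto = row.cyto_intensity + (
        rng.normal(0.0, spec.intensity_noise_sd, size=t.size)
        if spec.intensity_noise_sd > 0
        else 0.0
    )
    cyto = np.maximum(cyto, 1.0)
    nuc = ratio * cyto
    base = 300.0
    if row.marker_nuclear:
        m_nuc = base + spec.marker_contrast + rng.normal(0, spec.marker_noise_sd, t.size)
        m_cyt = base + rng.normal(0, spec.marker_noise_sd, t.size)
    else:
        m_nuc = base - 10.0 + rng.normal(0, spec.marker_noise_sd, t.size)
        m_cyt = base + rng.normal(0, spec.marker_noise_sd, t.size)
    return SingleCellTrace(
        cell_id=int(cell_id), times=t, nuclear=nuc, cytoplasmic=cyto, ratio=ratio,
        marker_nuclear_int=m_nuc, marker_cytoplasmic_int=m_cyt,
    )


def simulate_cohort_traces(
    truth: CohortGroundTruth,
    params: SensorModelParams | None = None,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Tidy table of measured traces for every cell in the cohort."""
    frames = [
        simulate_cell_trace(truth, cid, params, noise_sd).to_frame()
        for cid in truth.cells.cell_id
    ]
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class FrameSpec:
    """Geometry and intensity ranges of rendered synthetic frames.

    Cells are drawn as opaque disks (cytoplasm) with a concentric nuclear
    disk strictly inside; the flat ``background`` level fills pixels outside
    every cell, and Gaussian per-pixel noise of sd ``noise_sd`` is added to
    each channel.  Channels: ``nuclear`` (histone-like marker), ``sensor``,
    ``body`` (cell-interior proxy for a brightfield contour), and optionally
    ``cycle`` (cell-cycle marker) when the cohort carries marker states.
    """

    shape: tuple[int, int] = (384, 384)
    cell_radius_range: tuple[float, float] = (10.0, 14.0)
    nucleus_radius_range: tuple[float, float] = (3.0, 5.0)
    background: float = 0.0
    noise_sd: float = 3.0
    nuclear_marker_intensity: float = 500.0
    body_intensity: float = 300.0
    jitter_px: float = 1.0
    include_cycle_channel: bool = True
    max_placement_attempts: int = 500


@dataclass
class ImageStack:
    """Rendered multi-channel movie plus per-frame ground-truth label masks."""

    channels: dict[str, np.ndarray]  # name -> (T, H, W) float32
    nucleus_labels: np.ndarray  # (T, H, W) int32; label = cell_id + 1
    cell_labels: np.ndarray
    times: np.ndarray


def _place_cells(
    truth: CohortGroundTruth, frames: FrameSpec, rng: np.random.Generator
) -> pd.DataFrame:
    h, w = frames.shape
    n = len(truth.cells)
    placed: list[tuple[float, float, float]] = []
    radii_c = rng.uniform(*frames.cell_radius_range, size=n)
    radii_n = rng.uniform(*frames.nucleus_radius_range, size=n)
    margin_extra = 2.0 + 3.0 * frames.jitter_px
    for i in range(n):
        r = radii_c[i]
        ok = False
        for _ in range(frames.max_placement_attempts):
            y = rng.uniform(r + margin_extra, h - r - margin_extra)
            x = rng.uniform(r + margin_extra, w - r - margin_extra)
            if all(
                (y - py) ** 2 + (x - px) ** 2 > (r + pr + 2 * frames.jitter_px + 1.0) ** 2
                for py, px, pr in placed
            ):
                placed.append((y, x, r))
                ok = True
                break
        if not ok:
            raise GeometryError(
                f"could not place cell {i} of {n} after {frames.max_placement_attempts} "
                "attempts; use fewer or smaller cells or a larger field"
            )
    out = truth.cells.copy()
    out["y"] = [p[0] for p in placed]
    out["x"] = [p[1] for p in placed]
    out["cell_radius"] = radii_c
    out["nucleus_radius"] = radii_n
    return out


def render_frames(
    truth: CohortGroundTruth,
    frames: FrameSpec | None = None,
    params: SensorModelParams | None = None,
    times: Sequence[float] | None = None,
) -> ImageStack:
    """Render a cohort as a multi-channel time-lapse with ground-truth masks.

    In the sensor channel the cytoplasm of each cell carries its (constant)
    cytoplasmic intensity and the nucleus carries planted-ratio x cytoplasmic
    intensity, so with ``noise_sd = 0`` the mean nuclear / mean cytoplasmic
    intensity over the ground-truth masks equals the planted ratio exactly.
    Cell placements are rejection-sampled to be non-overlapping; positions
    jitter frame-to-frame by ``jitter_px`` (nucleus and cell move together).
    Updates ``truth.cells`` in place with planted positions and radii.
    """
    frames = frames or FrameSpec()
    params = params or SensorModelParams()
    t = np.asarray(truth.spec.times if times is None else times, dtype=float)
    rng = np.random.default_rng([truth.seed, 0x1F])
    cells = _place_cells(truth, frames, rng)
    truth.cells = cells
    n, (h, w) = len(cells), frames.shape
    nt = t.size
    ratio_traces = {
        int(row.cell_id): planted_ratio_trace(truth, int(row.cell_id), params, t)
        for row in cells.itertuples()
    }
    jitter = (
        rng.normal(0.0, frames.jitter_px, size=(nt, n, 2))
        if frames.jitter_px > 0
        else np.zeros((nt, n, 2))
    )
    want_cycle = frames.include_cycle_channel
    names = ["nuclear", "sensor", "body"] + (["cycle"] if want_cycle else [])
    channels = {nm: np.full((nt, h, w), frames.background, dtype=np.float32) for nm in names}
    nuc_labels = np.zeros((nt, h, w), dtype=np.int32)
    cell_labels = np.zeros((nt, h, w), dtype=np.int32)
    for k in range(nt):
        for i, row in enumerate(cells.itertuples()):
            cid = int(row.cell_id)
            cy, cx = row.y + jitter[k, i, 0], row.x + jitter[k, i, 1]
            cell_rr, cell_cc = draw_disk((cy, cx), row.cell_radius, shape=(h, w))
            nuc_rr, nuc_cc = draw_disk((cy, cx), row.nucleus_radius, shape=(h, w))
            lab = cid + 1
            cell_labels[k, cell_rr, cell_cc] = lab
            nuc_labels[k, nuc_rr, nuc_cc] = lab
            channels["body"][k, cell_rr, cell_cc] = frames.body_intensity
            channels["nuclear"][k, nuc_rr, nuc_cc] = frames.nuclear_marker_intensity
            cyto_int = row.cyto_intensity
            channels["sensor"][k, cell_rr, cell_cc] = cyto_int
            channels["sensor"][k, nuc_rr, nuc_cc] = ratio_traces[cid][k] * cyto_int
            if want_cycle:
                base = 300.0
                channels["cycle"][k, cell_rr, cell_cc] = base
                nuc_val = base + (truth.spec.marker_contrast if row.marker_nuclear else -10.0)
                channels["cycle"][k, nuc_rr, nuc_cc] = nuc_val
    if frames.noise_sd > 0:
        for nm in names:
            channels[nm] += rng.normal(0.0, frames.noise_sd, size=(nt, h, w)).astype(np.float32)
    return ImageStack(
        channels=channels, nucleus_labels=nuc_labels, cell_labels=cell_labels, times=t
    )


def spec_with(spec: CohortSpec, **overrides) -> CohortSpec:
    """Copy a spec with fields replaced (frozen-dataclass convenience)."""
    return replace(spec, **overrides)
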