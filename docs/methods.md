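# Methods

## Sensor model

The relocation sensor is modelled as four well-mixed pools — amounts
`Un, Pn, Uc, Pc` of un-/phosphorylated sensor in nucleus and cytoplasm —
with nuclear volume normalized to 1 and cytoplasmic volume `vol_ratio`:

```
dUn/dt = −k_phos·A·Un + k_dephos·Pn + k_imp·Uc/Vc + k_diff·(Uc/Vc − Un)
dPn/dt = +k_phos·A·Un − k_dephos·Pn              + k_diff·(Pc/Vc − Pn)
dUc/dt = −k_phos·A·Uc + k_dephos·Pc − k_imp·Uc/Vc − k_diff·(Uc/Vc − Un)
dPc/dt = +k_phos·A·Uc − k_dephos·Pc              − k_diff·(Pc/Vc − Pn)
```

Assumptions: phosphorylation and dephosphorylation occur with the same
rate constants in both compartments; only the unphosphorylated sensor is
actively imported; passive exchange moves both species down the
concentration gradient; no synthesis or degradation, so total sensor is
conserved exactly by construction (integration drift ≤ 1e-6 relative is
enforced by the integrator tolerances).  Transport fluxes act on
*concentrations* (rate constants in units of nuclear volume per minute),
which makes the zero-activity fixed point analytic:
ratio = 1 + k_imp/k_diff, independent of the volume ratio.

Kinase activity A(t) ∈ [0, 1] is the fraction of the kinase pool in the
active state.  Steady states solve the linear system `M(A)x = 0` under the
conservation constraint; the ratio is strictly decreasing in A whenever
k_imp, k_phos > 0, which makes the calibration curve invertible.  In the
limit of fast transport *and* weak import (k_imp ≪ k_diff) the enrichment
follows the unphosphorylated fraction:
ratio − 1 ≈ (k_imp/k_diff)·k_dephos/(k_phos·A + k_dephos); this is exact
at A = 0 and at k_imp = 0 for any rates.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| k_phos | 2.0 | 1/min | relocation ~2–3 min at full activity |
| k_dephos | 0.5 | 1/min | constitutive phosphatase tone |
| k_imp | 1.0 | 1/min | with k_diff gives 3-fold basal enrichment |
| k_diff | 0.5 | 1/min | passive exchange of a small reporter |
| vol_ratio | 7 | — | typical yeast cytoplasm:nucleus volume |
| total_sensor | 1 | a.u. | arbitrary; ratios are scale-free |

The published model's rate table is not available, so these defaults are
*calibration-constrained*, not literature values: they are pinned by two
observable behaviours of the reporter — ~3-fold nuclear enrichment in
unstimulated cells (fixing k_imp/k_diff = 2) and recovery of basal
enrichment within roughly 7 minutes after acute kinase inhibition (the
default rates give a 90 %-recovery time of 7.1 min; the tests only require
the 2–15 min window, treating the exact figure as kinetics-scale
calibration rather than a fitted constant).

### Activity profiles and fitting

A(t) is parameterized as a delayed exponential rise
`A0 + (Amax−A0)(1−e^−(t−t_on)/τ_rise)`, optionally multiplied by
`e^−(t−t_on)/τ_decay` for transient activation, clipped to [0, 1].  This is
the simplest family that reproduces step-like activation, delayed/slow
activation and transient bursts.  Fitting minimizes the sum of squared
differences between simulated and measured ratios with bounded least
squares (`scipy.optimize.least_squares`, trf), profile parameters only —
the sensor's rate constants are fixed inputs.  Three fixed starting points
(spread across fast/slow, high/low-plateau regimes) guard against local
minima; the fit is fully deterministic.  Measured ratios can exceed the
model's range because of noise, so steady-state inversion clips to [0, 1]
with a logged warning instead of raising.

When the pipeline infers activity from measured traces, the population-
median ratio is first rescaled so its basal level equals the model's
steady-state ratio at an assumed baseline activity (default 0.2,
reflecting nonzero basal signalling in unstimulated cells); absolute
enrichment varies between cells for reasons unrelated to kinase activity,
so only the trace's shape and relative depth are informative.

## Synthetic data generator

The generator emulates a field of yeast-like cells carrying the sensor,
a histone-like nuclear marker and optionally a cell-cycle marker:

* **Responder classes** with default fractions 0.72 / 0.11 / 0.17
  (responding / slow / non-responding), drawn multinomially.  Responding
  cells rise from baseline activity 0.2 to plateau 1.0 with τ_rise = 1 min
  at the stimulus (activity > 0.8 within ~3 min); slow cells start 5 min
  later with τ_rise = 8 min, so their planted initial response trails the
  final one by more than the 1.5× classification factor; non-responders
  show a transient burst (amplitude 0.5, 2-min decay) that returns to
  baseline — an early sensor exit followed by recovery — giving a final
  response near 0.
* **Basal heterogeneity**: per-cell basal ratio log-normal, median 3,
  log-sd 0.5 (IQR ≈ 2.1–4.2); per-cell multiplicative jitter on τ_rise
  (log-sd 0.15).  Traces are the model output rescaled to the cell's basal
  ratio.
* **Marker model**: nuclear-marker probability 0.7 / 0.3 / 0.2 per class
  (responding cells enriched for the G1-like nuclear state).  These
  probabilities are illustrative — chosen to reproduce the qualitative
  quadrant pattern, not fitted to data.
* **Noise**: additive Gaussian noise on the ratio (sd 0.05) and on
  intensities; rendered images add per-pixel Gaussian noise (sd 3 on
  intensities of order 200–500).

Rendered movies draw each cell as an opaque disk (constant cytoplasmic
sensor intensity, nucleus at planted-ratio × cytoplasmic intensity) on a
flat background (default 0), with frame-to-frame position jitter of 1 px.
Deliberate simplifications relative to real microscopy: no point-spread
blur (cells are large relative to pixels at this magnification), no
photobleaching, focus drift, cell growth or division, no autofluorescence
under the cells, and perfectly disk-shaped cells.  Passing tests therefore
validate the *pipeline's* correctness on data that satisfies its
assumptions; they do not certify segmentation robustness against
out-of-focus, overlapping or irregularly shaped real cells.

Everything is reproducible from (spec, seed); each cell uses its own
seeded random stream, so a cell's trace is independent of cohort order.

## Trace statistics

Formulas follow the standard relocation-reporter conventions: basal level
B = mean of the first three ratio points; normalized trace R(t)/B; final
response FR = 1 − mean of the last three normalized points; initial
response IR = 1 − mean of the three normalized points nearest the window
3–5 min post-stimulus (window configurable per experiment).  When sampling
is sparse and the window holds fewer than three points, the nearest points
are used, preferring the later on distance ties — under sparse sampling
the response has typically plateaued there, while an earlier candidate
still reflects pre-response lag.

Classification: FR < θ → non-responding; FR > 1.5·IR → slow; otherwise
responding.  Boundary conventions (chosen, since any convention is
defensible): FR = θ counts as responding, FR = 1.5·IR as responding, and
marker enrichment E = τ_m counts as marker-negative (strict >).
θ is either fixed at 0.2 (appropriate for cell-wall-stress experiments) or
derived as the 95th percentile of the final responses of a non-docking /
signalling-dead control population, which targets a 5 % false-positive
rate on genuinely unresponsive cells.  The percentile rule is this
package's choice of a reproducible threshold procedure.

Quality control keeps only cells tracked through the whole movie whose
nucleus area, cell area, nuclear-marker fluorescence and cellular sensor
fluorescence have coefficients of variation ≤ 0.2 (a concrete reading of
"low variability"; each bound is configurable).  Every rejection is logged
with the failing criterion.

## Image quantification

Nuclei: Otsu threshold (or fixed override for reproducibility) on the
nuclear-marker channel, 8-connected components, area filter 20–2000 px.
Cells: watershed region growing seeded at the nuclei and masked by the
thresholded cell-body channel — this replaces brightfield-based contour
detection, whose published algorithm is not specified; the contract that
matters downstream (exactly one cell region per nucleus, regions disjoint,
nucleus contained) is preserved.  A nucleus with no surrounding body
signal falls back to a dilated disk and is flagged.  Cytoplasm: cell minus
the nucleus dilated by a radius-2 disk ("expanded by two pixels" read as
radius-2 dilation); empty rings are flagged and their ratio is undefined.
Tracking: greedy nearest-centroid frame-to-frame assignment with a 10 px
displacement gate, ascending-distance order, ties to the lower label id;
unmatched objects start new tracks, and only full-length tracks enter the
analysis.  Quantification subtracts the per-frame median intensity outside
all cells (camera-offset proxy) before averaging over masks.

## Problem sizes and numerical choices

The test suite and acceptance script use: a 5×5×5 rate lattice for the
fixed-point/integration cross-check (tolerance 1e-6 relative); 21-point
calibration grids with monotone PCHIP inversion (round-trip error ≤ 1e-3);
36 one-minute frames per trace with the stimulus at 5 min; 300-cell
cohorts for classification recovery (multinomial 3σ bounds); 50-cell,
15-frame, 512×512 movies for segmentation fidelity (nucleus IoU ≥ 0.9,
cell IoU ≥ 0.85, mean ratio error ≤ 3 %); 20 replicates of 50-cell medians
for noisy profile recovery (≤ 10 % relative); and 1000-cell control
populations for threshold calibration.  These sizes were chosen so the
whole suite runs in minutes on a laptop while keeping the statistical
checks well-powered.  ODE integration uses LSODA with analytic Jacobian,
rtol 1e-8 and atol 1e-10 (tightened to 1e-10/1e-13 for the fixed-point
oracle).

## Known limitations

* The four phosphorylation sites of the real sensor are lumped into a
  single phospho-state; graded import inhibition is not modelled.
* Rate constants are calibration-constrained defaults, not measured
  values; inferred activities are therefore comparable within a parameter
  set, not absolute.
* The published headline percentages for real cell populations were
  measured on data that is not publicly available; the synthetic defaults
  plant the same mixture so the statistics pipeline can be validated, but
  recovering them here validates the software, not the biology.
* No watershed splitting of touching nuclei, sub-pixel localization or
  bleach correction; compartments are well-mixed (no spatial gradients).
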