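# skars — kinase-activity relocation sensor analysis

Synthetic kinase activity relocation sensors (SKARS) are engineered kinase
substrates: a docking site gives kinase specificity, a nuclear localization
sequence is inactivated by phosphorylation, and a fluorescent protein
reports where the sensor sits.  When the kinase (a MAPK such as yeast
Fus3/Kss1 or Mpk1) is active, the sensor leaves the nucleus; the
nuclear-to-cytoplasmic fluorescence ratio R(t) of each cell therefore
tracks kinase activity in real time.  This package implements the full
quantitative analysis for such experiments — and, because real microscopy
data for these sensors is not publicly deposited, it ships a ground-truthed
synthetic data generator so every stage is testable end to end.

It is intended for quantitative cell biologists analysing
nucleocytoplasmic-shuttling reporters in time-lapse microscopy.

## What it computes

**Compartment model** (`skars.model`).  The sensor exists as
un-/phosphorylated species in nucleus and cytoplasm.  With kinase activity
A(t) ∈ [0, 1] (fraction of the kinase pool active), phosphorylation rate
k_phos·A, constitutive dephosphorylation k_dephos, passive concentration-
equalizing exchange k_diff (both species) and active import k_imp
(unphosphorylated sensor only), the steady-state nuclear:cytoplasmic
concentration ratio decreases monotonically in A, with the closed form
ratio = 1 + k_imp/k_diff at A = 0 (defaults give the observed ~3-fold basal
enrichment).  The model supports forward simulation, a monotone
calibration curve ratio(A) and its inverse, and bounded least-squares
fitting of a parametric activity profile
A(t) = A0 + (Amax−A0)(1−e^−(t−t_on)/τ_rise) to a measured ratio trace.

**Trace statistics** (`skars.traces`).  Per cell: basal level
B = mean of the first three ratios; normalized trace R(t)/B; final response
FR = 1 − mean of the last three normalized points; initial response
IR = 1 − mean of three normalized points 3–5 min post-stimulus.  Cells are
classified as non-responding (FR < θ), slow (FR > 1.5·IR) or responding;
θ is fixed (0.2) or derived as the 95th percentile of a non-docking
control's FR distribution.  Population median/quartile summaries, heat-map
ordering, and cell-cycle-marker quadrant analysis
(enrichment E = nuclear − cytoplasmic marker intensity) are included.

**Image quantification** (`skars.segment`).  Nucleus segmentation by
thresholding the nuclear-marker channel, seeded region growing to cell
contours, cytoplasm = cell minus the nucleus dilated by 2 px,
nearest-centroid tracking, and per-mask mean-intensity extraction.

**Synthetic data** (`skars.synth`).  Cohorts with planted responder
classes (default 72 % responding / 11 % slow / 17 % non-responding),
log-normal basal enrichment (median 3), per-cell kinetic jitter, marker
states, measurement noise, and optional rendering to multi-channel image
stacks with ground-truth label masks.

## Worked example

```sh
python analysis/05_activity_inference.py --seed 1
```

generates a 100-cell responding cohort (planted baseline activity 0.2,
plateau 1.0, ~1 min rise), runs the pipeline and fits the activity profile
to the population-median ratio trace:

```
fitted baseline activity: 0.198 (planted 0.2)
fitted plateau activity:  0.984 (planted 1.0)
fitted rise timescale:    0.95 min
activity 3 min post-stimulus: 0.950
```

i.e. the inferred kinase activity rises from ~0.2 before the stimulus to
near-saturation within ~3 minutes, and both planted profile parameters are
recovered to within a few percent from noisy single-cell data.  The other
numbered scripts under `analysis/` cover the model's forward behaviour
(01), cohort generation (02), a segmentation benchmark against ground-truth
masks (03), and the single-cell responder classification with heat map and
marker quadrants (04); each writes its tables under `results/`.

The same stages are scriptable via the `skars` CLI (`skars run --config
config.yaml`, plus `synth`, `segment`, `traces` and `model` subcommands).

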