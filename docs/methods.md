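# Methods

This note documents the analysis model implemented by `trpquant`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the procedure leaves freedom.

## The measurement model

A ratiometric (Fura-2) calcium-imaging recording yields, for every cell, a
340/380 nm excitation-ratio time series sampled every 5 s (one image pair
per time point). The ratio is a monotone proxy for intracellular free
Ca²⁺; transient rises mark channel activation. Compounds are superfused in
known time windows (the *application schedule*): repeated applications of a
channel agonist — pregnenolone sulfate (PS) for TRPM3, capsaicin for TRPV1
— with a GPCR agonist (e.g. the µ-opioid-selective peptide DAMGO) overlaid
on one of them, and a high-K⁺ depolarizing solution at the end of the
experiment to identify neurons by voltage-gated Ca²⁺ influx.

### Trace conditioning

1. **Baseline**: the mean of the first 20 points (the first 100 s) is
   subtracted from the whole trace (`baseline_subtract`, `n_baseline=20`).
2. **Smoothing**: a centred running mean over 5 points (`smooth`,
   `window=5`). The window shrinks symmetrically at the trace edges so
   output length equals input length; this avoids padding bias at the cost
   of slightly less smoothing on the outer two points. Missing samples are
   excluded from each window mean.
3. **Amplitudes**: the response to an application is the maximum of the
   conditioned trace over the application window (`window_stat` with
   `max`; responses are upward transients), extended by a configurable
   post-application lag (default 2 frames = 10 s) to capture peaks that
   develop just after washout onset. Whether such peaks should count is a
   genuine free choice; the lag is exposed in `ClassificationParams`.

No drift correction is applied by default: baseline shift is a known,
uncorrected artifact source of this class of experiment, and the default
pipeline deliberately reproduces that behaviour. An optional
`linear_detrend` flag exists for exploration but is off in the standard
configuration.

### Classification

* **Neuron gate**: a cell is accepted as a neuron if its capsaicin *or*
  high-K⁺ amplitude is ≥ 0.1 ratio units; cells with neither application
  available are excluded.
* **Responder threshold**: amplitude ≥ θ_response = 0.1 ratio units
  (`classify_responder`); a 0.05 variant exists for experiments in which
  the agonist response is pharmacologically attenuated. The boundary is
  inclusive (≥).
* **Inhibition statistic**: with V_before, V_during, V_after the response
  amplitudes of the agonist applications immediately before, under and
  after the inhibitor,

      inhibition = 100 · (1 − 2 · V_during / (V_before + V_after)).

  Averaging the flanking responses corrects, to first order, for the
  rundown of responses across repeated applications. Two documented
  degeneracies are flagged rather than hidden: V_before + V_after = 0
  leaves the statistic undefined (NaN), and a cell that responds once and
  then never again (V_during = V_after = 0, V_before > 0) is reported as
  100 % inhibited — an artifact of the formula, carried as
  `inhibition_artifact`. Negative values (response grows under the
  inhibitor) are reported unclipped and retained in all averages.
* **Inhibitor sensitivity**: inhibition strictly greater than
  θ_inhibition = 7.5 %. The strict inequality follows the "larger than the
  threshold" reading; responder thresholds use ≥. Both conventions are
  documented here and configurable.
* **Flanking choice**: V_before/V_after come from the agonist applications
  immediately preceding and following the overlapped one. A cell whose
  recording lacks the following application is excluded from the
  inhibition analysis rather than imputed.
* **Subgroups**: agonist-sensitive neurons are partitioned 2×2 by
  capsaicin sensitivity × inhibitor sensitivity (`subgroup_2x2`); the four
  counts always sum to the agonist-sensitive total.

### Group statistics

Averaged traces and bar values are reported as mean ± SEM with single
cells as biological replicates (SEM = SD/√n, ddof = 1). Percentages are
rounded half-away-from-zero at the requested number of decimals. Cell-size
histograms use half-open 2 µm bins [2k, 2k+2) and a strict > 31 µm
large-cell cutoff. Two-group comparisons use the two-sided Mann-Whitney
test (unpaired) or Wilcoxon signed-rank test (paired); p-values are exact
when both n ≤ 25 and the data are tie-free, otherwise the normal
approximation with tie correction. Significance stars: * for
0.01 ≤ p < 0.05, ** for 0.001 ≤ p < 0.01, *** for p < 0.001. Multi-group
comparisons use Kruskal-Wallis (independent) or Friedman (repeated
measures) followed by Dunn's multiple-comparison test. The Dunn post-hoc
is implemented directly (pooled-rank z statistics with tie correction for
the independent design, within-block ranks for the repeated design) with
classical Bonferroni adjustment; the adjustment variant is a free choice
and Bonferroni was chosen as the most conservative classical option.

Dose-response curves are fit by least squares with a variable-slope Hill
function R(d) = bottom + (top − bottom)/(1 + (IC50/d)^h). For
percent-inhibition data, bottom and top are bounded to [0, 100];
initialisation takes bottom/top from the data extremes and the IC50 from
the first dose whose response crosses the midpoint. A Spearman-correlation
direction guard flags data whose trend contradicts the declared direction,
and an IC50 outside the tested dose range is flagged. Non-convergence is
reported, never silently replaced.

### Imaging front end

Ratio images are (F340 − bg)/(F380 − bg) per pixel; pixels whose
background-subtracted **380 nm** (denominator) intensity does not exceed
the intensity threshold are masked, since the threshold's purpose is to
avoid low-intensity division artifacts. Background estimation is
configurable: a user-supplied background ROI (per-frame mean), a constant
per channel, or the 1st percentile of each frame as a fallback; the exact
ImageJ plug-in behaviour is not published, so the threshold has no silent
default for image-based runs — it must be set explicitly in the run
configuration. ROI traces are per-frame means over the unmasked ROI
pixels; a fully masked frame yields a missing value. Feret's diameter is
the maximum caliper distance over the ROI boundary (the major axis for an
ellipse), computed on the convex hull of the boundary point set; ellipse
boundaries are discretised at 720 points, giving sub-pixel accuracy.
Coordinates are pixel-centred, 0-based, row-major.

### Electrophysiology

Voltage ramps (1 mV/ms, one sweep per 1–2 s) are analysed offline at fixed
potentials, by default −80 and +80 mV. All potentials are liquid-junction-
potential corrected: the stored command voltage minus the LJP (15 mV in
the standard solutions; 0 in Cs⁺-free mode), so the "−80 mV" sample is
read where the command voltage equals −65 mV, linearly interpolated
between the bracketing samples. Sweep-level current is a single
interpolated sample — no local averaging — so closed-form checks on ohmic
synthetic data are exact. Currents are divided by cell capacitance to
current densities (pA/pF), baseline-subtracted (per-potential mean over a
pre-agonist window), and gated by a minimum-response criterion: the
agonist-evoked baseline-subtracted current must exceed 10 pA in magnitude
in the stated direction (inward for sensory-neuron recordings). The same
inhibition statistic as for imaging is applied per potential; capacitance
cancels, so currents and densities give identical inhibition. Evaluation
sweeps default to: last sweep before inhibitor onset, first sweep ≥ 5 s
after onset (the block develops in under 5 s), first sweep ≥ 2 s after
washout; explicit times can be passed instead. Series-resistance
compensation and capacitance-transient removal are assumed already done by
the acquisition system.

## The synthetic-data generator

`generate_population` draws labels along the hierarchy
neuron → PS-sensitive → (capsaicin-, inhibitor-sensitive) and builds each
ratio trace as baseline + response kernels + linear drift + i.i.d.
Gaussian noise. The default configuration encodes a large mixed-culture
experiment: 3,576 neurons; 614/3576 PS-sensitive; among PS-sensitive
cells 479/614 capsaicin-sensitive, with inhibitor sensitivity 465/479
among capsaicin-positive and 97/135 among capsaicin-negative cells (the
two sensitivities are strongly associated, so the conditional fractions
are parameterised separately; setting them to `None` falls back to a
single marginal fraction). Among PS-insensitive neurons 1289/2962 are
capsaicin-sensitive.

* **Amplitudes**: single-cell response amplitudes are not published as
  numbers (only the 0.1 ratio-unit threshold is); defaults are chosen well
  above threshold — PS and capsaicin mean 0.5 ± 0.1 ratio units (truncated
  at 0), high-K⁺ 1.0 — values typical of strong agonist responses in
  Fura-2 recordings.
* **Kernel**: the 5 s sampling is prescribed, the transient shape is not.
  The kernel rises linearly over 3 frames, stays at plateau for the
  application window, and decays exponentially (τ = 6 frames) with the
  decay shifted/scaled to reach exactly zero 18 frames (90 s) after
  washout. The compact support means applications spaced ≥ 90 s apart do
  not bleed into each other, which keeps the noise-free examples exact;
  window-maximum statistics are insensitive to the precise kinetics.
* **Rundown**: the k-th application of a compound is scaled by
  rundown_factor^(k−1), default 0.9 — a moderate decline typical of
  repeated agonist applications. Inhibitor-sensitive cells have responses
  in inhibitor-overlapping windows multiplied by 1 − inhibition_depth
  (default 0.5).
* **Noise and drift**: i.i.d. Gaussian noise on the ratio (default
  SD 0.05, a 10:1 amplitude-to-noise ratio) and an optional linear drift
  (default 0). The noise-free constructed inhibition of every cell is
  recorded as `true_inhibition` before noise is added.
* **Diameters**: neurons N(22, 4.5) µm clipped to [8, 45] — a
  small-diameter nociceptor population — and non-neurons N(14, 3) µm.
* **Default schedule**: PS at 120–180, 270–330 and 420–480 s, the
  inhibitor at 250–350 s (covering the second PS application), capsaicin
  at 570–600 s and high-K⁺ at 690–720 s, always last. Gaps of 90 s match
  the kernel support.
* **Images**: `render_image_stacks` writes 16-bit stacks in which each
  cell's 380 nm intensity is constant and the 340 nm intensity above
  background is ratio(t) times the 380 nm intensity above background, so
  the imaging front end recovers the input traces up to integer
  quantization. Overlapping ellipses are rejected to keep the ROI ground
  truth unambiguous.
* **Ramps**: `generate_ramp_recording` produces a command ramp from −100
  to +100 mV (−115 to +85 mV after the 15 mV LJP correction) with either
  an ohmic or a Boltzmann-type outwardly rectifying conductance, gated on
  during agonist windows and scaled by a known factor during inhibitor
  windows.

What the generator does **not** emulate: photobleaching, focus drift and
cell movement; spontaneous activity, oscillations and spike trains;
correlated (pink) noise; partial or graded single-cell sensitivities;
series-resistance artifacts. Tests passing on synthetic data therefore
demonstrate that the analysis chain recovers the generating structure
under its own assumptions (additive Gaussian noise, stereotyped
transients, binary sensitivity labels) — they do not certify performance
on recordings violating those assumptions, e.g. cells with strong
spontaneous transients inside evaluation windows.

## Problem sizes and determinism

The test suite and the acceptance script regenerate all inputs
programmatically. The full-scale classification-recovery check simulates
3,576 cells (≈ 150 frames each) and runs in a few seconds; the ramp cohort
uses 12 cells at 90 sweeps × 201 samples; dose-response fits use 8-point
series. All randomness flows through `numpy.random.default_rng` seeded
from explicit configuration fields, so identical configurations produce
bit-identical traces, labels, stacks and report tables.

## Known limitations

* The inhibition statistic's rundown correction is first-order: with
  rundown factor r it reports 100·(1 − 2r/(1 + r²)) ≈ 0.55 % (r = 0.9)
  residual "inhibition" for a completely insensitive cell. This bias is
  inherent to the statistic, well below the 7.5 % sensitivity threshold,
  and deliberately not corrected.
* Responder classification uses the first inhibitor-free application of a
  compound; cells that recruit sensitivity during a recording are not
  modelled.
* The Feret diameter of a pixel-set ROI is computed over pixel centres;
  values can differ from a corner-based convention by up to 1 px.
* No absolute [Ca²⁺] calibration, no automated segmentation, no motion
  correction, and no reader for vendor acquisition formats (inputs are
  CSV/TIFF).
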