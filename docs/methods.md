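# Methods

`seatbcg` implements an unconstrained heartbeat-monitoring chain for a
16 × 16 pressure sensor mat strapped to the backrest of a driving seat and
sampled at 30 Hz. The driver's back presses a subset of the 256 cells;
cardiac ejection shakes the trunk (ballistocardiography), superimposing a
small periodic oscillation on the static contact pressure. The chain has
three stages: recognise the driving posture from the static pressure
distribution, extract the cardiac component per sensor by frequency-domain
band-pass filtering, and pick the one sensor whose extracted signal best
matches an ECG-like reference. Because the posture determines where the
back touches the mat, the optimal monitoring sensor is posture-dependent,
and two leaning postures make the signal non-extractable altogether.

## Synthetic plant

No public recordings exist for this kind of mat, so the package ships a
simulator that generates the data the pipeline assumes, with ground truth
attached.

**Static templates.** Each of six postures is a deterministic 16 × 16 map:
a rotated anisotropic Gaussian contact patch with an optional lateral skew.
Postures 1–4 differ in contact height, spread and peak pressure
(2.3–2.8 V, peaking above 2 V as real seat-contact voltages do); postures 5
and 6 are posture 1 leaned 10° left/right — the contact mass moves about
three columns sideways and the loading becomes asymmetric (different
spread, peak and rotation on the two sides, as a belted driver loads the
two bolsters differently). Cells above 0.4 V form the *contact mask*.

**Cardiac coupling.** Each contact cell reads

```
v_s(t) = base_s · subject_scale
         + coupling_scale · c_s · w(t) + ε_s(t),   ε ~ N(0, noise_sd²)
```

with `w(t)` a unit-amplitude waveform at the heart rate (sine by default; a
Gaussian pulse train is available) and `c_s` the coupling gain. The gain
follows the static pressure (`c_s ∝ base_s`, which is what makes the
power-spectrum peak map mirror the mean-pressure map) multiplied by a
localised emphasis `0.3 + 0.7·exp(−d²/2σ²)`, σ = 0.75 cells, centred on
the contact peak: mechanical transmission of the heartbeat is strongest
directly behind the heart, and this makes the optimum sensor unique and
clearly dominant rather than a statistical tie among neighbouring cells.
At the lean postures the coupling is attenuated by 0.003 — the trunk rests
on the bolster, decoupling the cardiac vibration from the mat — which
drives every correlation below the non-extractability floor.

**Defaults** (the study conditions): 60 s at 30 Hz, heart rate 77 bpm,
`noise_sd` = 5 mV, subject scale drawn uniform in [0.85, 1.15] for dataset
generation (an adult weight span of roughly ±15%). The classification
dataset is 10 subjects × 20 groups × 6 postures = 1200 frames, each a
template with per-subject scale, 3% per-frame multiplicative jitter and
20 mV additive frame noise. The reference trace is an R-spike train
(Gaussian bumps, σ = 40 ms, 2% amplitude jitter, 2 mV noise) phase-locked
to the embedded waveform; only its periodicity and phase matter, since the
correlation stage band-filters it anyway. A clean, electrode-grade
reference is assumed: heavy reference noise caps every sensor's attainable
correlation at a common ceiling and turns best-sensor selection into a
coin flip among the top cells.

**What the plant does not model:** vehicle vibration and body movement,
respiration, heart-rate variability, PQST morphology of the ECG, sensor
drift or quantisation. Passing tests therefore demonstrate that the
algorithms are correct under the stated signal model, not that the method
is robust to road noise.

## Posture features and classifier

Frames are rendered as colour maps (fixed 0–3 V range, bilinear ×16
upsampling to 256 × 256, a fixed blue-to-red colormap with monotone
luminance so thresholding segments the blob cleanly), then processed by the
classical chain: ITU-R 601 grayscale → 3 × 3 median filter → Otsu
binarisation → largest 8-connected component. Nineteen features follow, in
a fixed documented order:

1. geometry — contact-blob circumference (Moore-traced chain length,
   diagonal steps √2), area (pixels), roundness `4πA/P²`, Hu moments 1–7;
2. texture — gray-level co-occurrence energy, entropy and inertia
   (16 levels, distance 1, four directions, symmetric, normalised), each
   summarised by mean and population SD across the four directions;
3. colour — mean R, G, B over the blob.

Each feature column is normalised by the maximum absolute value seen in the
training split (`q* = q / max|q|`; zero columns pass through).

The classifier is an extreme learning machine: hidden weights and biases
uniform on [−1, 1], sigmoid activation, output weights solved in one step
as the minimum-norm least-squares solution `β = H⁺T` (SVD pseudoinverse,
relative cutoff 1e-12) against one-hot targets; prediction is arg-max with
ties to the smallest class. Defaults are 70 hidden nodes and 600 training
samples, the knee of the accuracy/size trade-off in the sweep
(`accuracy_sweep` reproduces the full grid: 100–800 samples × 30–120
nodes).

## Heartbeat extraction

Filtering is brick-wall DFT masking: transform, zero all bins outside the
pass band (the DC bin is always dropped — static load is never cardiac),
inverse transform. The per-sensor *peak map* is the maximum of the
one-sided periodogram `P(f) = |X(f)|²/T` inside the band (ties to the
lowest frequency).

The default band is the general cardiac band, 30–120 bpm converted
physically (`f = bpm/60`) with a 0.05 Hz margin: 0.45–2.05 Hz. Two reasons:
no per-subject heart-rate prior is needed, and a beat-width band (a few
DFT bins at 60 s) makes band-limited white noise itself quasi-sinusoidal,
raising the lag-searched correlation of *pure-noise* sensors to ~0.7 and
destroying the contrast between coupled and uncoupled cells; with ~96 bins
in the wide band the noise floor stays near 0.25. A `paper-literal`
conversion mode (`f = bpm/100`) is kept because parts of the application
literature print the 75–80 bpm range as 0.75–0.8 Hz; the physical mode is
the default. No tapering is applied before the DFT (1800 samples, leakage
negligible for this purpose).

## Sensor selection

The reference trace is band-filtered with the same band (and linearly
resampled first if its rate differs), then every sensor's filtered signal
is scored by the absolute Pearson correlation maximised over integer-sample
lags within ±0.8 s (about one beat period) — the mechanical-to-electrical
delay between pressure and ECG is physiological and otherwise unmodelled.
The best sensor is the arg-max (ties to the lowest index); a posture is
*extractable* when the best correlation reaches the threshold, default
0.6 — strictly between the non-correlation floor (< 0.4) and the weakest
usable contact correlation (≈ 0.9). Constant inputs return correlation 0
with a warning.

## Numerical and design notes

- Sensor indexing is row-major from the top-left of the mat, 1-based;
  helpers convert to (row, col). The physical orientation of sensor 1 is a
  convention, not observable from the data.
- Otsu's constant-image fallback: all-foreground with threshold
  `value − 1`. Single-pixel blobs report circumference 0 and roundness 0;
  their enclosing rectangle is the 1 × 1 unit square.
- The minimum-area enclosing rectangle is computed over pixel corner
  points (each foreground pixel a unit square) by rotating calipers on the
  convex hull, so an axis-aligned w × h block reports sides exactly (w, h).
- GLCM matrices are tabulated by hand over pixel pairs lying entirely
  inside the component mask (library co-occurrence routines do not support
  masks); "mean/SD" of each texture statistic is taken across the four
  directions, the only population available for a single image.
- Model files, recordings, frames and tables are delimited text at 17
  significant digits (exact double round trip; table readers use
  round-trip float parsing); writes are atomic (temp file + rename) and
  every artifact embeds the tool version and seed/config hash in comment
  headers.
- All randomness flows through explicitly seeded `numpy` generators;
  identical seeds give bit-identical recordings, datasets and models.

## Problem sizes

Default experiment sizes are the study design itself: the 1200-frame
dataset with a 600/600 split for the classifier (10 repeats for the
reported mean) and single 60 s recordings per posture for extraction and
selection; the whole acceptance run completes in well under a minute of
compute. Unit tests use shorter recordings (2–20 s) where only algebraic
properties are at stake.

## Known limitations

- The six templates are stylised single-blob distributions; real pressure
  images show two scapular lobes and richer texture. The feature stage
  would carry over, but the reported accuracies apply to the synthetic
  plant only.
- The correlation stage assumes the reference and recording share a time
  base to within a beat; clock drift between devices is not modelled.
- Extraction needs the heart rate to lie inside the configured band;
  rates outside 30–120 bpm require a custom band.
- The basic ELM is used; class-imbalanced or weighted variants are out of
  scope, as are heart-rate-variability analysis and fatigue scoring.
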