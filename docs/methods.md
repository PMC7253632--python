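# Methods

`nirsmap` implements a complete analysis chain for blocked-task prefrontal
fNIRS group classification: synthetic cohort generation, modified
Beer–Lambert conversion, Butterworth band-filtering, robust-GLM channel
activation scoring, topographic temporal-feature map rendering, and
cross-validated CNN classification. This note records the models, the
parameters that matter, and the design decisions taken where the design was
genuinely open.

## Signal model and synthetic cohorts

Each channel's oxygenated-haemoglobin change (ΔHbO, μM) during a trial is

    y(t) = a · r(t) + ε(t),

where `r(t)` is the unit-peak expected response — a 60 s task boxcar
convolved with the canonical double-gamma haemodynamic impulse response —
and `a` is the channel's response amplitude. The impulse response is the
difference of two gamma densities (unit scales, undershoot ratio 1/6)
with shape constants chosen so the response lobe peaks at 6 s and the
undershoot at 16 s after onset, peak-normalized. All constants are
exposed in `HRFParams`.

The generator emulates a two-group study: `n_impaired = 15` and
`n_control = 9` subjects, three tasks × three trials (60 s task + 30 s
rest, epochs of ⌊90 × 8.138⌋ = 732 samples at 8.138 Hz), 48 channels.
Controls receive a base amplitude of 0.5 μM (a typical prefrontal task
response); the impaired group's amplitude is scaled by
`amplitude_ratio_impaired` (default 0.6 — a free effect-size dial, not an
estimated quantity). Per-(subject, channel) amplitudes are jittered
log-normally (σ = 0.4) so that thresholded activation tables are partial
rather than all-or-nothing. ΔHbR is generated as an anticorrelated mirror
of the ΔHbO response (factor 0.3) with its own noise, so the Beer–Lambert
round trip is exercisable; the analysis itself uses ΔHbO only.

The noise model per channel is a sum of cardiac (≈1 Hz), respiratory
(≈0.25 Hz) and Mayer-wave (≈0.1 Hz) sinusoids with per-channel random
phases, a linear drift, and white noise. Defaults (0.3 / 0.2 / 0.15 μM,
0.002 μM/s, 0.1 μM) give realistically contaminated raw traces. The
`NoiseSpec.low()` condition used by the parameter-recovery studies is
defined by *in-band* power: after the 0.001–0.1 Hz band-pass the entire
white-noise floor folds into the analysis band, so "low" must be set
against the band-limited signal, not the raw trace; its values
(white SD 0.005 μM, oscillation amplitudes 0.004–0.01 μM) leave residual
noise an order of magnitude below response-induced feature values.

What the generator does **not** emulate: motion artifacts,
short-separation (scalp) channels, spatially correlated physiology,
subject-level vascular idiosyncrasies beyond amplitude jitter, and any
true lesion topography — active channels are spatially unstructured. A
passing recovery test therefore shows that the pipeline recovers a known
amplitude contrast under its own assumptions, not that comparable accuracy
would be reached on clinical recordings.

All randomness derives from `CohortSpec.seed` through per-(stage, subject,
task) seed sequences; identical specs give bit-identical datasets.

## Beer–Lambert conversion and filtering

Optical-density changes at 780/850 nm map to (ΔHbO, ΔHbR) through the 2×2
modified Beer–Lambert system with extinction coefficients from a standard
compilation of haemoglobin absorption spectra (0.736/1.102 and
1.058/0.691 cm⁻¹ mM⁻¹), differential pathlength factor 6.0 at both
wavelengths, and 3 cm source–detector separation — all overridable. The
system is solved exactly per sample; the forward/inverse round trip is
accurate to 1e−9 (relative).

Physiological noise is removed by a cascade of 4th-order Butterworth
high-pass (0.001 Hz) and low-pass (0.1 Hz) filters, zero-phase — a
phase-shifting filter would invalidate time-point features such as "the
map at 15 s". The cascade is realized in the frequency domain as the
exact squared magnitude response |H_hp|²·|H_lp|² on a mirror-padded
segment, the steady-state equivalent of forward–backward (filtfilt)
filtering. A time-domain forward–backward IIR pass is avoided on
purpose: the 0.001 Hz corner implies a filter time constant of minutes,
longer than the recordings, and its start-up transients dominate the
output (measured: a stop-band 1 Hz tone retained ~25% of its RMS through
`sosfiltfilt` regardless of padding, versus the ~1e-8 the Butterworth
response prescribes).

**Filter placement.** The continuous recording is filtered before
epoching by default; per-trial-segment filtering (each 90 s epoch with
its 2 s baseline margin) is a config switch, used automatically for
inputs that arrive already epoched. With the frequency-domain filter the
two placements give matching trial responses (measured 20–60 s slope of
the noiseless unit response: −0.00022 in continuous mode for every trial
position, −0.00026 epoch-wise). This equivalence is itself diagnostic: a
time-domain filtfilt realization produces trial-position-dependent slope
offsets an order of magnitude larger than the response's own plateau
slope, purely from start-up transients.

Epochs are trial-relative (t = 0 at task onset, sample index = round(t·fs),
0-based); baseline correction subtracts the mean of the 2 s before onset
(configurable).

## Activation GLM and ROI selection

Each channel–trial epoch is regressed on the design regressor (the same
unit-peak expected response): `y = β₀ + β₁·dHRF + ε`. Fitting uses
iteratively reweighted least squares with the Tukey bisquare influence
function (tuning constant 4.685, MAD scale) via `statsmodels.RLM`; plain
OLS is available (`glm.method: ols`) and doubles as the test oracle. The
activation statistic is t₁ = β₁/SE(β₁) with df = 732 − 2 = 730.

A channel is an ROI ("activated") channel when t₁ strictly exceeds the
critical value t_crt = 1.9632 — the *two-sided* 0.05 Student-t quantile at
730 df used in a one-sided comparison. This mixed convention is reproduced
deliberately; its channel-wise false-positive rate under the null is
α/2 = 0.025, which the calibration tests assert. A consistent one-sided
rule (`convention: upper_tail`, null rate α) is also implemented. No
multiple-testing correction is applied across channels, matching the
procedure the package models.

ROI sets gate only the temporal-raw samples; feature maps are rendered
from all 48 channels (optionally zeroing non-ROI channels,
`maps.zero_non_roi`).

## Temporal features and map rendering

Per-channel features of the 90 s epoch: ΔHbO at 13 time points (5…65 s in
5 s steps), interval means (5–65 s, 5–25 s), least-squares slopes (5–15 s,
20–60 s, 60–70 s — the last extends past the 65 s analysis bound by
design and stays inside the epoch), and population-moment skewness and
kurtosis over 5–65 s (kurtosis is the fourth standardized moment: normal
⇒ 3). Interval endpoints are inclusive in sample indices.

The 48 channel values are interpolated to a 200×200 grid by barycentric
(linear) interpolation on a Delaunay triangulation of the montage
positions, nearest-neighbour fill outside the convex hull — precomputed
once per layout as a sparse weight operator, so rendering is monotone in
every channel value and reproduces planes exactly inside the hull. The
packaged default montage is a 6×8 grid spanning the prefrontal band
(unit square, FpZ-anchored, small fixed jitter for triangulation
robustness); any layout CSV (`channel,x,y`) can be substituted. No numeric
montage coordinates are published for the hardware this emulates; any
fixed, consistent layout preserves the spatial pattern information the
classifier consumes.

Image value scaling is a per-feature affine map [min, max] → [0, 1] with
clipping, computed **on the training folds only** within each CV fold and
then applied frozen to the test fold. Per-image min-max scaling is
rejected because it would erase the between-group amplitude difference
that drives classification. Temporal-raw samples (one per ROI channel per
trial) are the 732-sample series linearly resampled to 200 points and
broadcast down 200 rows.

## The CNN

Two convolutional blocks (8 kernels 4×4, stride 1, no padding → ReLU →
2×2 max-pool → dropout), flatten, FC-128 + ReLU, 2-way softmax;
categorical cross-entropy with Adam. Size chain for 200×200 inputs:
200 → 197 → 98 → 95 → 47, flatten 47·47·8 = 17,672; 2,263,570 parameters.
Pooling uses floor semantics (incomplete trailing windows dropped). The
network is implemented directly in NumPy (im2col convolutions,
index-tracked pooling, inverted dropout) with analytic gradients verified
against finite differences; it is CPU-friendly and bit-reproducible given
a seed.

An input-normalization stage subtracts the training set's mean intensity
before the first convolution (fitted with the weights, applied identically
at prediction time). On low-contrast maps whose pixel values share a
positive bias this matters: without centring, some weight inits drive the
first ReLU stage dead and training stalls at chance; with it, training is
stable across seeds.

Training hyperparameters are free parameters (the procedure this package
models does not state them): learning rate 1e−3, batch 8, dropout 0.25,
epochs 50 by default. The dropout rate was set by a train/eval-consistency
check: at 0.5, spatial dropout of the smooth, low-contrast maps drives
training loss to ~0 while evaluation-mode predictions collapse to one
class (the two modes' activation statistics diverge); at 0.25 both modes
behave. The desk-scale studies (acceptance script, heavy tests) train 15
epochs per fold — the point where fold training reliably converges on
separable maps — as their stated problem size.

## Cross-validation and metrics

Folds are random over samples by default (k = 5), which mirrors the
modelled procedure but lets trials of one subject span folds;
subject-grouped folds are provided and are what the parameter-recovery
studies use. The difference matters: on a null cohort (amplitude ratio
1.0) sample-mode CV scores far above chance because the network memorizes
per-subject amplitude fingerprints — a leakage demonstration, not a
discovery of signal. Metrics (accuracy, recall, precision, F1, all %) are
computed per fold from pooled confusion counts (impaired = positive
class), then averaged across folds; undefined entries (empty
denominators) are reported as NaN and excluded from averages. F1 is
computed per fold and averaged, not reconstituted from averaged precision
and recall. For null-effect checks the package also reports pooled
*balanced* accuracy: with a 15:9 class imbalance, plain accuracy's chance
level is the 62.5% majority prior, while balanced accuracy's is 50%
regardless of the prior; and because trials of one subject receive
strongly correlated predictions, chance bands should use subject-level
effective sample sizes.

Group time-course comparison: per subject, the mean ΔHbO curve over that
trial's ROI channels, averaged over trials; groups are compared by a
two-sample t-test (Welch by default, pooled optional) on the 5–65 s window
means.

## Numerical choices and degenerate inputs

- Exactly collinear GLM input (zero residuals) would zero the robust MAD
  scale; such fits return infinite t-values rather than dividing by zero.
- A constant regressor, empty fit lists, single-class training folds,
  zero-variance moment windows, NaN channel values and non-invertible
  extinction matrices raise immediately with specific messages.
- Prediction ties break to the lower class index; argmax over softmax.
- Sub-seeds derive from the global seed via SHA-256 of stage labels
  (`stable_seed`), all below 2³¹.

## Known limitations

- The synthetic generator's simplifications (above) mean recovery results
  bound what the pipeline can do under ideal assumptions only.
- The NumPy CNN targets tiny datasets; it makes no attempt at GPU-scale
  throughput or data augmentation.
- Epoch-wise filtering trades the continuous recording's stationary noise
  statistics for trial-transient consistency; with long inter-trial
  intervals and event-related designs the continuous mode may be
  preferable.
- Sample-mode CV is kept as the default for fidelity to the modelled
  procedure despite its leakage; reports should state the fold mode.
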