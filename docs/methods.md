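# Methods

This note documents the models, algorithms and numerical choices behind
`ictalesi`, and what the synthetic benchmarks do and do not demonstrate.

## Neural mass model of ictal oscillations

Each cortical region is a four-population mean-field unit (pyramidal cells,
excitatory interneurons, slow dendritic and fast somatic inhibitory
interneurons).  Synapses convert firing rate to membrane potential with the
impulse response

    h(t) = Q q t e^(-q t),  t >= 0,

where `Q` is the synaptic gain (`A`, `B`, `G` in mV for the excitatory,
slow-inhibitory and fast-inhibitory populations) and `q` the rate constant
(`a`, `b`, `g`; accepted in ms^-1 as conventionally printed and converted to
s^-1 internally).  `h` peaks at `t = 1/q` with value `Q/e` and integrates to
`Q/q`.  Potentials convert back to rates through the sigmoid
`S(v) = 2 e0 / (1 + exp(r (v0 - v)))` with the canonical constants
`e0 = 2.5 s^-1`, `v0 = 6 mV`, `r = 0.56 mV^-1`.

The state equations are five second-order ODEs (ten states), each of the
form `y'' = Q q (input) - 2 q y' - q^2 y`, with connectivity constants
`C = 135`, `c1..c7 = (1, 0.8, 0.25, 0.25, 0.3, 0.1, 0.8)`:

* `y0` — pyramidal output PSP, driven by `S(y1 - y2 - y3)`;
* `y1` — excitatory input PSP, driven by `p(t) + c2 C S(c1 C y0)`;
* `y2` — slow-inhibitory PSP, driven by `c4 C S(c3 C y0)` with gain `B b`;
* `y3` — fast-inhibitory PSP, driven by `c7 C S(c5 C y0 - c6 C y4)` with
  gain `G g`;
* `y4` — slow-inhibitory PSP at the fast interneurons, `S(c3 C y0)` with
  gain `B b`.

The recorded channel is `y1 - y2 - y3`, the net PSP at the pyramidal
population, which is proportional to the region's equivalent current
dipole.  The extrinsic drive `p(t)` is Gaussian white noise with mean
90 s^-1 and SD 30 s^-1, drawn once per integration step.

Integration is Euler–Maruyama at a fixed 1 ms internal step, decimated by
plain subsampling to the requested output rate (the synaptic second-order
dynamics act as a low-pass filter, so aliasing above the 50 Hz Nyquist of
the 100 Hz benchmark rate is negligible).  The first 2 s are discarded as
burn-in.  Identical parameter set and seed give bit-identical traces;
non-finite states raise with the offending parameter set.  Regime switches
(test design 1) swap the parameter vector at a chosen step with the state
carried over, producing a continuous trace.

## Regime classification

Traces are labeled with six regime types: (1) normal background,
(2) sporadic spikes, (3) sustained spike discharges, (4) rhythmic activity,
(5) low-voltage rapid activity, (6) quasi-sinusoidal oscillation.  Features:
line length (mean |first difference| x sample rate), major frequency
(Welch argmax of the detrended trace in 0.5–45 Hz), baseline voltage
(median), amplitude (95th percentile of |detrended|), spectral
concentration (power within ±1 Hz of the major frequency / total 0.5–45 Hz
power), and transient-peak statistics (strict local maxima above baseline +
3 x MAD; their rate and inter-peak-interval coefficient of variation).

The decision table, in order: type 1 if amplitude < 2 mV; type 5 if major
frequency > 12 Hz; type 6 if concentration > 0.85; type 2 if peak rate in
(0, 2) Hz; type 3 if rate >= 2 Hz with regular intervals (CV < 0.3);
else type 4.  All thresholds are config-exposed
(`ClassifierThresholds`).  The concentration threshold was set at 0.85
because harmonic-rich regular spike discharges concentrate ~0.7 of their
power near the fundamental while genuinely sinusoidal regimes reach ~0.98;
a 0.5 cut would fold the former into type 6.  With these defaults the
reduced exploration grid (below) produces all five ictal families.

## Parameter exploration and banks

The exploration grid is `B` 2–60 mV by 2, `G` 2–30 mV by 2, `a`
0.05–0.15 ms^-1 by 0.01, `b` 0.025–0.075 ms^-1 by 0.005, `g` 0.2–1.6 ms^-1
by 0.2, with `A = 5.5 mV` fixed.  Exploration is two-stage: each (B, G)
pair is first simulated at midpoint rate constants (a = 0.1, b = 0.05,
g = 0.8 ms^-1) and pairs producing normal activity are dropped; the
surviving pairs receive the full (a, b, g) grid search.  Simulations are
batched (vectorized across parameter sets), which makes the reduced grid
(every 4th value per axis, 576 simulations) run in seconds.

Banks are balanced to a configured count per ictal type (10,000 at full
scale, 50,000 total, split 40,000 train / 10,000 test).  Candidates of each
type are divided between the train and test pools *before* resampling, so
no parameter set appears on both sides; pools smaller than their quota are
resampled with replacement.  Per-type quotas follow the train/test
proportion with largest-remainder rounding, making the split sizes exact.

## Head model

The source space is an icosphere (radius 78 mm) parcellated by
farthest-point seeding and nearest-seed assignment into contiguous,
roughly equal-area regions; each region carries one radially oriented unit
dipole at its (re-projected) centroid.  Radial orientation is the natural
choice on a sphere where no cortical surface normals exist.

Scalp potentials come from the analytic solution for a dipole inside three
concentric homogeneous shells — brain/skull/scalp radii 87/92/100 mm,
conductivities 0.33/0.0042/0.33 S/m.  Per Legendre order the radial
potential in shell *j* is `A_j r^n + B_j r^-(n+1)`; continuity of potential
and radial current at the two interfaces plus the insulating outer boundary
give a 5x5 linear system per order; the series is truncated at n = 60 with
a geometric tail bound checked below 1e-6 of the partial sum (the measured
truncation error against a 300-term reference is ~1e-6 relative).  With
equal conductivities the solution collapses to the classical
homogeneous-sphere dipole formula, which the tests verify to well below
0.5 % through an independent generating-function closed form.  The
76-channel montage uses standard 10-10 template directions radially
projected onto the scalp shell; all lead fields are common-average
referenced (every column sums to zero).  Externally computed lead fields
(e.g. boundary-element models on real anatomy) can be loaded from delimited
tables and are validated and re-referenced on load.

## Synthetic sources and datasets

A sample is a contiguous patch of 2–10 regions grown by uniformly random
frontier expansion from a random center.  Half the samples (configurable)
split the patch into a grown center group and the remaining neighbor
group, each with its own waveform drawn from the bank — emulating phase
differences and dynamics changes after local propagation; the other half
share one waveform patch-wide.  Inactive regions are exactly zero.  Sensor
data are the lead-field projection plus white Gaussian channel noise
calibrated to a matrix-wide SNR of 5, 10, 15 or 20 dB; source and sensor
matrices are independently max-abs scaled to [-1, 1].  Background regions
are silent and noise enters only at the sensors, consistent with
specifying the sensor-level SNR alone.

Held-out evaluation uses two designs: (1) single-waveform patches whose
regime switches to a different ictal type at a uniformly random time
(state carried over); (2) two-dynamics patches like the training
distribution.  Test parameters come exclusively from the bank's test
split.

What the generator does not emulate: spatially correlated background
activity, non-white sensor noise, cortical folding (dipole orientation
variability), volume-conductor anisotropy, seizure propagation over time
and multifocal sources.  Passing benchmarks therefore demonstrate correct
implementation and the learnability of the inverse map under these ideal
conditions, not clinical-grade performance.

## Inverse network

The network maps channels x T to regions x T.  A per-time-step residual
fully connected stack (entry layer to the working width, ReLU, then
width-preserving residual blocks) learns a spatial denoising/inverse
operator; a stack of residual LSTM layers integrates over time (helpful at
phase cancellations where single topographies are ambiguous); a linear
per-time-step readout emits region waveforms.  There is no output
activation: targets lie in [-1, 1] and a saturating nonlinearity would
flatten the MSE gradient.  The temporal stage is sequence-length agnostic.

Training minimizes MSE with Adam (defaults: learning rate 3e-4, weight
decay 1e-6, batch 64) with a 5 % validation split grouped by patch — all
SNR copies of a patch stay on one side, preventing leakage — and the
best-validation parameters are restored.  The implementation is pure
NumPy with hand-derived backpropagation (spatial layers, LSTM with
batched input projections, Adam); the analytic gradients are checked
against central finite differences in float64 to 1e-5 relative error.
Initialization is seeded (Glorot-uniform dense layers, uniform
±1/sqrt(H) LSTM with forget bias +1), and all data generation, splitting
and batching are driven by explicit seeds, so training and inference are
bit-reproducible.

## Classical baselines

* **sLORETA** — minimum-norm kernel `M = L^T (L L^T + lambda I)^+` with the
  estimate standardized by the resolution diagonal
  `s_i = (M y)_i / sqrt((M L)_{ii})`.  The automatic regularization is
  `lambda = trace(L L^T) / (n_channels * SNR_amp^2)` with an assumed
  amplitude SNR of 3; noiseless tests use a vanishing lambda, where the
  estimator's zero-localization property is exact.
* **LCMV beamformer** — unit-gain weights
  `w_i = C^-1 l_i / (l_i^T C^-1 l_i)` on the data covariance diagonally
  loaded by 5 % of its mean eigenvalue.
* **FDI** — per-channel DFT, the bin nearest the dominant ictal frequency;
  sLORETA applied to the real- and imaginary-part topographies; per-region
  maps combined as the complex magnitude (phase-shift invariant).

For the time-domain methods the spatial map is the mean of the absolute
per-time maps at the peaks of the dominant oscillation (strict interior
local maxima of the max-energy channel above 0.5 x its global maximum);
absolute values prevent cancellation between peaks of alternating
polarity.

## Ictal imaging pipeline

Preprocessing: zero-phase 4th-order Butterworth band-pass 0.5–40 Hz
(applied forward-backward), common-average re-reference, extraction of the
first 3 s after onset, max-abs normalization.  The dominant ictal
frequency is, in automatic mode, the 1–40 Hz argmax of the channel-averaged
Welch post/pre onset power ratio (flagged low-confidence when the ratio is
flat); a manual value can always be supplied and takes precedence, which is
the faithful clinical mode.  The narrowband stage is a zero-phase band-pass
at `f0 ± min(2.5, f0/2)` Hz — a total passband of at most 5 Hz that stays
positive at low frequencies.

Processing order is part of the contract and is asserted by tests: the
network consumes the broadband segment and its *output* waveforms are
narrowband-filtered before the per-region energy map is formed; the
classical methods receive narrowband-filtered *input*.  Spatial maps are
per-region energies over the window, delineated with Otsu's 256-bin
histogram threshold.  Spike imaging averages the reconstruction energy in
a 100 ms window centered on the spike peak (clipped with a warning at
segment edges).

## Evaluation metrics

On the Otsu-thresholded estimate set `Ŝ` against truth `S` in a space of
`|Ω|` regions: sensitivity `|Ŝ∩S|/|S|`; specificity `1 − |Ŝ∖S|/|Ω∖S|`;
precision `|Ŝ∩S|/|Ŝ|`; F1 = harmonic mean of precision and sensitivity;
harmonic/geometric means of (sensitivity, specificity).  Localization
error is the symmetrized mean nearest-centroid distance between `Ŝ` and
`S`; spatial dispersion the energy-weighted mean distance of suprathreshold
regions to `S`; the seizure-onset-zone error the mean of the two directed
average-minimum distances between electrode points and estimated
centroids.  All distances are Euclidean between centroids (no cortical
mesh exists for geodesics) and reported in mm.  Temporal correlation:
in simulation mode the maximum Pearson r of each estimated region against
the true waveforms, averaged over estimated regions; in clinical mode the
r between the mean estimated waveform and the max-energy channel.  No lag
search in either mode.  Degenerate cases (empty estimate, constant map or
waveform) are reported as zeros with explicit flags or raised, never
silently.

## Benchmark problem sizes

The recovery benchmark runs on a 200-region sphere with the 76-channel
montage: a bank from the every-4th-value grid balanced to 120 sets per
type, 5,000 patches x 4 SNR levels = 20,000 training samples of 0.5 s at
100 Hz, a network with spatial width 128 (2 residual blocks) and one
residual LSTM layer of 128 units, trained 6 epochs at learning rate 1e-3;
held-out evaluation uses 60 patches per test design at 4 SNR levels
(240 samples each).  These sizes were chosen so the whole benchmark runs
in a few minutes on a single CPU core while leaving clear margins over the
acceptance thresholds (mean correlation and specificity >= 0.9, SNR spread
<= 0.05); the full-scale configuration of record (994 regions, 500 Hz,
1.24M samples, width-500 network with 3 recurrent layers) is expressed by
the same code paths via `ModelConfig`/`DatasetConfig` defaults and is
GPU-scale work.

## Known limitations

* The spherical geometry flattens source depth variation; localization
  errors on real cortical anatomy will be larger, especially for mesial
  sources.
* Radial-only dipoles ignore orientation ambiguity, which classical
  methods in particular benefit from here.
* The NMM parameter exploration is deliberately not exhaustive; it seeks
  coverage of waveform families, not a bifurcation atlas.
* Automatic dominant-frequency selection is a convenience stand-in for
  expert review; the manual mode is authoritative.
* Training at the full published scale is supported but not exercised by
  the test suite; the benchmark demonstrates the scaled configuration
  only.
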