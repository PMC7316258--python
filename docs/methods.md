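# Methods

## The problem

A fixed 16-hydrophone array (four 4-hydrophone panels splayed along the
curved wall) listens to a half-cylindrical pool, 33.5 m in diameter, that
is strongly reverberant: a whistle-like tonal lasting 0.3–1 s overlaps
with many of its own wall, floor and surface echoes at every hydrophone,
so any single time-difference-of-arrival (TDOA) estimate between a
channel pair may lock onto an echo rather than the direct path.
Geometric localizers (multilateration from TDOAs) then fail not because
the estimates are noisy but because some are *wrong*.

The approach implemented here is to hand a supervised learner an
overabundance of delay-related "clues" per sound — one GCC-PHAT TDOA
estimate for each of the 120 channel pairs, plus the central ±17 ms of
the normalized circular cross-correlation of every pair including
self-pairs (136 × 6601 values) — and let training at known source
positions discover which clues are reliable *in this particular
acoustical environment*. A random forest performs high-feature-volume
classification and, through out-of-bag (OOB) permutation importance,
feature selection; compact classifiers (CART, linear/quadratic SVM, LDA)
and per-axis Gaussian-process regressors then run on the reduced set.
Steered-Response Power (SRP) and Spherical Interpolation (SI) provide
the geometric baselines.

## Coordinates, environment, sound speed

Origin at the center of the first array's panel, z up, meters. The
panels hang 1.60 m below the surface, so the water surface is z = +1.60;
the pool footprint is the closed lower half of a circle of radius
16.75 m centered at (15.7, 3.87). The as-built floor depth is not
public; it is a config parameter defaulting to 7.0 m below the surface,
which contains the deepest source station (z = −4.27).

Sound speed comes from the Del Grosso (1974) seawater polynomial (Wong &
Zhu 1995 restatement; pressure in kg/cm², hydrostatic conversion
≈ 0.1024 kg/cm² per m). At the recorded pool conditions — 26.04 °C,
31.5 ppt, essentially zero depth — it evaluates to 1533.05, i.e. ~1533
m/s, the value used throughout.

## Tonal synthesis

Each tonal is defined by six parameters (duration X, cycle count n,
center frequency Fc, cycle amplitude A, phase start α, onset/decay
fraction P) plus a waveform kind. The instantaneous-frequency trace is
sinusoidal, f(t) = Fc + A·sin(2π·n·t/X + α); the phase is its integral,
Φ(t) = 2π∫f. Rendering is either y = A(t)·sin(Φ) or the arcsine
heuristic y = A(t)·arcsin(m·sin Φ)/arcsin(m) with m = 0.8, which makes
the waveform more triangular and adds a weak odd-harmonic stack. A(t)
ramps as sin²(2πt/(4XP)) over [0, XP], holds 1, and mirrors for decay.
Two values per parameter (0.3/1 s; 1/2 cycles; 6/10.5 kHz; 2/5 kHz;
±π/2; 0.1/0.25) give 64 permutations × 2 kinds = 128 tonals.

Design choices here:

* **α acts inside f(t).** A pure carrier-phase offset would leave the
  spectrogram trace unchanged and could not make tonals distinct; the
  published example trace (α = −π/2 starting at its frequency minimum)
  matches the FM-phase reading. A `carrier_phase_offset` flag also adds
  α to the carrier for the literal reading.
* **Phase is integrated numerically** (trapezoidal cumulative sum at the
  output rate), so arbitrary frequency traces can later be swapped in;
  the Hilbert-based oracle test confirms the re-derived f(t) agrees
  within 1 Hz RMS at 192 kHz.
* If 2XP > X the onset and decay windows simply multiply; the default
  grid never triggers this.

Playback tracks prepend a 0.25-s, 2-kHz leader tone exactly 2 s before
the tonal onset (5-ms cosine edge tapers avoid clicks).

## The pool simulator (synthetic-data generator)

Reflections are modeled with the image-source method. Reflecting planes
are the surface (pressure-release, coefficient −0.95), the floor (+0.7),
the straight dividing wall, and the curved wall approximated by 32
tangent facets (+0.8, all frequency-independent, all configurable).
Curved-surface imaging has no closed form; tangent facets converge with
facet count and keep the simulator fast. Candidate images are enumerated
breadth-first up to `max_reflection_order` (default 2 → 1226 candidates),
excluding immediate same-plane re-reflections; gains multiply per
bounce. Each candidate is then subjected to the standard specular
validity test per receiver: the unfolded reflection path must intersect
every reflecting surface inside its physical extent (the pool footprint
for surface/floor, the diameter strip for the dividing wall, the
angular sector × depth strip for each facet). This test is what makes
the facet approximation converge — without it every facet would
contribute a bogus full-strength arrival and the echo energy would grow
with facet count instead of approaching the single specular reflection
a concave wall produces. A mid-pool source typically yields 1 direct +
~4 first-order + ~9 second-order arrivals per hydrophone. Each channel's impulse response places gain/(distance) at delay
distance/c using an order-32 Hann-windowed-sinc fractional-delay
stencil, so simulated TDOAs are not quantized to samples; channels are
rendered by FFT convolution.

Ambient noise is seeded Gaussian with RMS `noise_rms` relative to the
clean reverberant channel RMS, so SNR_dB = −20·log10(noise_rms); the
default 0.1 corresponds to 20 dB. The speaker was rope-suspended and
swayed; the generator draws each recording's true source uniformly in a
horizontal disk of radius 1/3 m about its nominal station. A dataset is
one row per (station × tonal): 14 × 128 = 1792 recordings at full
scale, each fully determined by the manifest (nominal and swayed
coordinates plus a per-recording child seed), so identical seeds yield
bit-identical datasets.

What the generator does *not* emulate: frequency-dependent absorption,
speaker directivity, moving sources, the holding-pool gates, and real
impulse-response calibration (none was published). Passing tests on this
data therefore demonstrate the pipeline's correctness and its behavior
under controlled multipath and noise — not performance on any real pool.

## Snippets and partition

Leader tones are detected on channel 1 by a normalized matched filter
(template correlation over local energy, ~1 for a clean leader, ~0.005
noise floor; detection threshold 0.2 tolerates multipath phase
cancellation, which we observed can pull the statistic to ~0.45).
Each snippet is the 2-s window starting 1.5 s after a leader onset, so
a ≤1-s tonal played 2 s after the leader sits fully inside. Snippets
are band-passed zero-phase (order-6 Butterworth, forward–backward) to
[Fc − A − 0.5 kHz, Fc + A + 0.5 kHz]; the band comes from the known
spec rather than a detector since labels exist.

The 90/10 train/test split is stratified per source station, with
sinusoid/triangular siblings of the same parameter permutation always
co-assigned; per station the test side receives max(1, round(0.10 ×
n_sibling_groups)) groups.

## Features

897,856 values per snippet: 120 GCC-PHAT TDOAs (pairs i<j, lexicographic)
followed by 136 sliced cross-correlations (pairs i≤j, lag-ascending).
Correlations are circular over the 384,000-sample snippet (a linear,
zero-padded variant sits behind a flag); all 136 series share one
normalization divisor — the largest absolute value among them — so
amplitude information is suppressed (per-series normalization is a
flag). The central 6601 lags span ±3300 samples ≈ ±17.2 ms, enough for
every first-arrival TDOA in the pool. PHAT whitening floors bin
magnitudes at 1e−12 of the maximum to avoid blow-ups in filtered-out
bands. TDOAs are argmax-at-integer-sample; the sign convention (negative
when the pair's first channel leads, matching the geometric
(d_i − d_j)/c) is pinned by delayed-copy tests. The featurizer never
sees labels.

## Models

**Random forest.** A bagging layer over sklearn CART trees
(`max_features="sqrt"` per split, bootstrap per tree; the non-standard
~75%-subsample variant is a flag). OOB accuracy is tracked cumulatively
against tree count. Feature importance is the *permuted variable delta
error*: the mean over trees of the OOB error increase when one feature's
OOB values are permuted (unscaled). Only features a tree splits on can
affect its predictions, so the scan covers each tree's used-feature set —
the delta is identically zero elsewhere — making the computation
tractable at ~900k features. Features with strictly positive importance
form the reduced set.

**Classifier suite.** CART limited to 20 splits (via a 21-leaf budget),
linear SVM, quadratic (degree-2 polynomial) SVM with one-vs-one
decomposition, and LDA; SVM/LDA see train-set z-scored features, trees
see raw ones. Stratified k-fold cross-validation (10 folds, capped at
the smallest class count) precedes a refit on all training data.

**Gaussian-process regression.** One GP per axis on z-scored reduced
features, kernel = constant × RBF + white noise, hyperparameters by
marginal-likelihood maximization with a seeded restart. The RBF length
scale is initialized at the median pairwise distance of the scaled
training inputs (bounds two decades either side): with thousands of
input dimensions, distances concentrate far from unity, and a unit
initial scale reliably drives the optimizer into the degenerate
predict-the-training-mean regime. *Standard*
evaluation predicts test snippets from all training stations;
*leave-location-out* retrains on 13 stations and predicts the held-out
station's test snippets, aggregated over all 14 — the long-distance
interpolation probe. With only two depths represented, depth-axis
interpolation is expectedly poor, and the evaluation shows exactly that
(Z error dominating lateral error).

**Parsimonious analysis.** The ≤20-split tree's used features (at most
41 by the tree-structure bound, in practice far fewer) are the
parsimonious set; a forest retrained on them yields importances that are
summed within hydrophone pairs (16×16 symmetric) and averaged within
array pairs (4×4). Off-diagonal array-pair mass indicates cross-array
delay information — the geometric signature of TDOA-style reasoning.

## Baselines

**SRP.** The pool is gridded into cubes (default edge 15 cm, corners
outside the footprint skipped); a corner's score sums, over the 120
pairs, the pair's circular cross-correlation at the corner's expected
TDOA rounded to the nearest sample; the argmax corner wins, ties broken
by smallest grid index and reported. PHAT weighting is available but not
default. A known limitation, documented rather than patched: for these
band-limited tonals the correlation oscillates at the carrier, so the
corner score surface is sharply multimodal and a 15-cm grid undersamples
it; anechoic single-snippet errors of ~0.1–1 m depending on where the
swayed source falls relative to the grid are normal, and errors shrink
as the cube edge does. An optional `lag_window` (scored as the maximum
correlation within ±W samples of the expected lag) is provided for users
who want the robust-SRP variant; it is off by default because the
reference method is the plain corner lookup.

**Spherical Interpolation.** With range differences δ_j = d_j − d_1 from
the reference-channel TDOAs, the source position and range satisfy the
linear system 2(s_j·x) + 2δ_j R = |s_j|² − δ_j², solved jointly by least
squares; exact on consistent inputs, and invariant to any common clock
offset by construction.

## Error reporting

Localization error is summarized as the median of absolute deviations
("MAD" in this field's usage — *not* median(|x − median x|), hence the
code name `median_abs_error`) with the 25th–75th percentile IQR of the
same deviations; quantiles interpolate linearly between order
statistics. Classification accuracy carries a 95% Wilson score interval
(statsmodels). Distribution commentary uses scipy's Anderson-Darling and
Kruskal-Wallis plus a compact Dunn's mean-rank post-hoc with Bonferroni
correction (no installed package provides Dunn's test).

## Scales used by the test suite

The full study (14 stations × 128 tonals) is desk-computable but slow;
the suite exercises the pipeline at reduced, fixed scales chosen once:

* **Reverberant recovery run:** 14 stations × 16 tonals (the 2×2×2
  duration/cycles/center-frequency sub-grid at cycle amplitude 2 kHz,
  phase −π/2, onset fraction 0.1 — every 8th permutation — both
  waveform kinds), reflection order 2, 20 dB SNR, 300 trees, seed 0.
* **Anechoic degenerate run:** 14 stations × 8 tonals (every 16th
  permutation), order 0, noiseless — the problem is then exactly
  geometric and all classifier classes should be perfect.
* Oracle checks use a single anechoic playback of the worked-example
  tonal (0.3 s, 2 cycles, 10.5 ± 2 kHz) from a swayed P10 source.

These scales are the package's own choices for a deterministic,
repeatable suite; nothing about the method depends on them.

## Known limitations

* Facet-approximated curved wall: image positions are exact only in the
  facet limit; reflection coefficients are uncalibrated guesses.
* The generator's channels are perfectly matched (exact 1/r spreading,
  identical gains) and its echoes are ideal impulses. Per-channel
  energy ratios and local direct+echo interference are therefore
  stronger cues than in a real rig, and the parsimonious tree exploits
  them: its used-feature set concentrates on self-pair and within-array
  correlations rather than the cross-array delay features a real
  deployment's parsimonious models favor. The forest's wider importance
  map over the reduced set does include cross-array pairs.
* A 20-split CART tree does not perfectly classify snippets of held-out
  tonal parameter groups even on anechoic, noiseless data (the SVMs and
  LDA do); a greedy split-budgeted tree generalizes worst across tonal
  types, consistent with the tree being the weakest model class in
  studies of this design.
* Random-forest accuracy degrades sharply below ~10 training snippets
  per station (p ≫ n with ~900k features); the toy smoke config in the
  tests deliberately accepts this.
* SRP grid quantization as described above.
* Nothing here has been validated against real dolphin whistles; the
  featurization assumes a clean, singly-voiced fundamental within a
  known band.
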