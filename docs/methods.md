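# Methods

## The system being modelled

A steady-state visual evoked potential (SSVEP) brain–computer interface
encodes a data vector as the amplitudes `A_m` of many simultaneous flicker
frequencies `f_m = f0 + m·δf` of a single LED:

    x(t) = Σ_m A_m cos(2π f_m t),      period T = 1/δf.

The visual cortex responds at the driven frequencies and, through its
intrinsic nonlinearity, at their pairwise sums and differences.  The
package implements the full computer side of such an interface — encoding,
band planning, decoding, scoring, and a classifier whose mixing layer is
the cortex itself — plus a phenomenological forward model of the cortex
that stands in for a human participant in training loops and tests.

## Forward model

The simulated EEG spectrum is a susceptibility-weighted harmonic expansion

    y~(ω) = Σ_{n=1..N} χ~⁽ⁿ⁾(ω) · FT[(σ·x + ξ)ⁿ](ω)  + noise,

implemented order-by-order as `irfft(χₙ(f) · rfft(xⁿ))`.  Defaults:

| parameter | default | meaning |
|---|---|---|
| `chi1` | 1 (flat) | first-order gain; tabulated profile optional |
| `chi2_scale` | 3.0 | amplitude of the second-order susceptibility |
| `chi2_decay` | 10 Hz | decay of the universal `exp(−f/decay)` profile |
| `max_order N` | 2 | harmonics + pairwise intermodulation only |
| `gain_sigma σ` | 1.0 | overall input gain (second order scales as σ²) |
| `noise_white_sd ξ` | 0.01 /sample | input-referred perturbative white noise |
| `background_scale` | 0.15 | colored output noise amplitude |
| `background_slope` | 1 | `1/f^slope` background power |
| `background_knee` | 1 Hz | low-frequency flattening of the background |
| `alpha_center/height/width` | 10 Hz / 0.8 / 1 Hz | Gaussian alpha-rhythm bump |
| `output_white_sd` | 0.02 /sample | white measurement floor |

Amplitude units are arbitrary (EEG gain is unknown); only ratios matter.
The calibration reproduces the qualitative regime of recorded spectra under
the package's encoding convention (below): first-order comb lines roughly
two orders of magnitude above the background in power, the intermodulation
band clearly resolved but much weaker than first order, a stimulus-free
record dominated by the alpha peak.  Two parameters deserve comment:

* **`background_knee`.** A pure `1/f` background makes the periodogram of a
  60 s record largest at its lowest bin (~0.017 Hz), which would put the
  no-stimulus spectral maximum at DC rather than at the alpha rhythm.
  Resting EEG backgrounds flatten at very low frequency; the 1 Hz knee
  implements that with one parameter.
* **`chi2_scale`.** The decaying-exponential *shape* of the second-order
  susceptibility is universal, but its absolute scale relative to first
  order is a free parameter of the model.  It is set to 3.0 so that the
  intermodulation lines of balanced two-band combs stand cleanly above the
  background, the contrast that measured intermodulation spectra display;
  at 1.0 the simulated channel destroys most of the class information that
  the classification experiments rely on (a logistic-regression probe on
  the noisy intermodulation line powers caps at 0.72 test accuracy versus
  0.85 at scale 3, where it saturates).

Orders n ≥ 3 run through the same machinery (reusing the second-order
profile) but are outside the validated regime; the default is N = 2.

**Encoding convention.** Simulations drive the model with zero-mean combs
normalized to unit total power per band — binary image vectors are scaled
to unit power, and the data/control bands of the classifier are
balance-normalized (Σ A² = 1 each), as the physical experiment prescribes.
This gives every task one amplitude scale, so the single noise calibration
above covers image transmission and classification alike.  The affine
mapping of the waveform to [0, 1] (constant mean light intensity) is
applied only when exporting LED drive signals; the decoder is
scale-invariant, so this convention changes no decoded value.

**Fast line-level simulator.** Training loops evaluate thousands of
stimulus→spectrum passes, so alongside the full time-domain simulator there
is a line-level path that computes the sum-band response directly on the
discrete sum grid: amplitudes `(π/2)·χ²(f)·conv(σX+ξ, σα+ξ)` plus a complex
Gaussian per bin whose variance equals the periodogram level a record of
the same length would show.  Noise-free, it is exactly the analytic
sum-frequency spectrum, which in turn is tested to match the DFT of the
time-domain simulation to better than 1e-6 relative error.  The
time-domain path remains available everywhere (`sim="time_domain"`).

## Decoding

NPSDs are rectangular-window periodograms of an integer number of comb
periods, so every encoded line falls on an exact DFT bin (zero leakage);
longer records average disjoint one-period segments (Welch).  The DC bin is
discarded and the spectrum normalized to unit maximum.  Image pixels are
the NPSD powers at the comb bins, renormalized by the maximum over the
comb's own bins; for binary images power and amplitude readout coincide
after this normalization.  SSIM uses a single global window with K1 = 0.01,
K2 = 0.03, L = 1 and sample (n−1) covariances, matching the reference
implementation evaluated with one full-image window.  The
mutual-information bit rate is a deliberately simple plug-in estimator:
threshold reconstruction and truth at 0.5, estimate `I(B̂;B)` from the 2×2
pixelwise confusion matrix, scale by pixels per second.  It discounts
wrongly transmitted pixels but ignores spatial correlations.

## The physical neural network

The classifier mixes a data comb (band a) with a trainable control comb
(band b); the band plan guarantees the sum band `[f_a+f_b, f_a+f_b+2·bw]`
is disjoint from both input bands and both second harmonics (narrowband
contract `center_a + bw < center_b < 2·center_a − bw`, plus an explicit
pairwise-disjointness check).  The readout restricts the NPSD to the sum
band, renormalizes, optionally squares it (quadratic readout), and takes
the power fraction in each of `n_classes` contiguous segments.

**Segment placement.** The default partition is equal-width.  Because the
intermodulation profile of two combs is triangular (the number of line
pairs summing to each frequency peaks at band center), equal width
structurally favors the middle segment; `calibrate_segment_edges` instead
places the interior edges so a featureless input splits its power evenly
— the calibration an experimenter would perform before training.  The
classification experiments use calibrated edges (single-layer accuracy on
the 3-class task rises from 0.43 to 0.70 noise-free).

**Training.** A genetic algorithm (population 32, tournament 3, uniform
crossover 0.7, per-gene Gaussian mutation sd 0.1 at rate 0.1, elitism 1,
all configurable) searches control amplitudes in [0,1]^P.  Noise
realizations are frozen per training sample (common random numbers), so
fitness is deterministic and the elite trace monotone.  Fitness options:
mean log-probability of the true class (default; floored at 1e-3 so one
zero-power segment cannot dominate), accuracy, and mean correct-class
probability.  The last is used for the two-layer experiment because it is
the metric that experiment reports — cross-entropy actively avoids the
probability sharpening that the second layer provides, since sharpening
makes confident errors costly.

**Two-layer stacking.** Two stacking rules are implemented.  The literal
rule (`stack="lines"`) rigidly translates the first layer's sum-band line
powers into the second layer's data band, preserving relative values.  In
simulation this rule never beat the single layer: the class-independent
triangular envelope dominates the re-encoded comb, and the second
convolution smooths away the per-line class signal while adding fresh
noise.  The default rule (`stack="readout"`) re-encodes the first layer's
readout — its `n_classes` segment powers — as a short comb.  The second
mixing then implements a trainable quadratic map on the first readout
(output power is quadratic in the re-encoded values), which both remaps
systematic confusions and sharpens the probability vector; with the
quadratic readout flag on the second layer the sharpening is fourth-order.
The two-layer network is trained jointly (concatenated genome), warm-started
from the trained single-layer solution.

At the default settings (45 training / 30 test samples, 3 Gaussian classes
in 5 features quantized to 2 bits, population 32, 40 generations, 10
seeds), the two-layer network improves the mean correct-class probability
from ≈0.44 to ≈0.60 on every seed, with correctly classified samples at
0.81–0.86 — the ~80 % regime the stacked system is known to reach, while
the single layer stays near 0.45.

**Attention.** Attentional disruption is modelled as a multiplicative gain
in (0, 1] on `chi2_scale`; sum-band power scales with gain², and the
readout probability of the trained class decays toward chance as the gain
drops.  The human-subject statistics of the attention experiment are out of
scope.

## Synthetic data

`make_digits` draws binary stroke-template digits (0, 1, 7) at 8×8 or
14×14, with optional independent pixel flips (the `noise_sd` rate) and
optional ±`jitter`-pixel translation (default off: a whole-image shift
translates the encoded comb and moves intermodulation mass between readout
segments more than class identity does).  `make_iris_like` draws three
Gaussian clusters in the unit cube over 4–5 features, with a separation
knob (0 collapses the centroids; classes 1 and 2 overlap more than class
0, as in the classic flower-measurement table).  All generators are
bitwise-reproducible per seed.  These fixtures emulate the shape and
difficulty profile of the real datasets, not their distributions: passing
tests show the pipeline's mechanics and the model-level claims, not
performance on real handwriting, real flowers, or real EEG.

## Numerical choices and problem sizes

* Comb periods are forced to an integer number of samples
  (`sample_rate / δf` integral); 996 Hz serves the 12 Hz-bandwidth image
  task (T = 49/3 s), 200–512 Hz the classification and oracle tests.
* Band-interval overlap uses open intervals (shared endpoints are
  disjoint), matching the brute-force oracle in the tests.
* The analytic sum-frequency spectrum carries the (π/2)·χ²·[X∗α]
  convolution weight per ordered line pair; the time-domain cross term
  `2·x_X·x_α` has cosine amplitude χ²·ΣA_mB_n, so DFT amplitudes are
  compared after multiplying by π/2.
* Default problem sizes keep every experiment desk-scale: image task
  196 lines × 16 periods; digit classifier 64+64 lines, 12 training
  images; two-layer task 10+10 and 3+3 lines, 75 samples, 10 seeds.
* Degenerate inputs: all-zero amplitude vectors cannot be balanced
  (error); a zero-power sum band yields uniform probabilities with a
  warning; candidate genomes that cannot be evaluated receive −∞ fitness.

## Known limitations

* The forward model is phenomenological: no biophysics, no electrode
  geometry, no artifacts (blinks, EMG), no inter-subject variability
  beyond the seed.
* The χ² absolute scale and all noise amplitudes are calibrated to
  qualitative features of published spectra, not fitted to data.
* Orders n ≥ 3 are mechanically supported but unvalidated.
* The mutual-information rate is a lower-bound-style pixelwise estimator.
* Only two layers are exercised; the interfaces allow chaining more.
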