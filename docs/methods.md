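# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `temposample`. Everything quantitative stated here is
computed by the package's tests, examples or acceptance script.

## Stimulus model

**SNR sampling functions.** A trial's visibility trajectory is
`x(t) = Σ_f a_f sin(2π f t + φ_f)` over f ∈ {5, 10, …, 55} Hz with
amplitudes a_f ~ U(0, 1) and phases φ_f ~ U(0, 2π), sampled on the 24-frame
grid (120 Hz) and affinely rescaled to min 0, max 0.75. At 24 samples /
120 Hz the DFT bin spacing is exactly 5 Hz, so every component sits on a
bin: the pre-normalization waveform has zero power off the 5–55 Hz grid and
at the 60 Hz Nyquist bin, and the normalization can only add a DC term. A
degenerate flat draw (all amplitudes ≈ 0) would make the rescaling divide by
zero; the generator re-draws from the same stream (the probability of the
branch triggering is negligible, but the failure mode would be silent).

**Word images.** Words are drawn in DejaVu Sans (packaged with matplotlib;
a freely redistributable sans-serif with metrics configurable through
`GlyphSpec`), cropped to the ink bounding box, and rescaled so the word
spans 3.4 deg and the font x-height 0.75 deg, centered on an 8.9 × 8.9 deg
white field at a default 32 px/deg. Glyph metrics are enforced to ±10%.

**Spatial filtering.** The bandpass is the standard radial image-domain
Butterworth, `|H(f)|² = 1 / (1 + ((f² − f_l f_h)/(f W))^{2n})` with
`W = f_h − f_l` and default order n = 2. This is the one common bandpass
form whose half-power points fall exactly at the two printed cutoffs with
gain ≈ 1 at the printed center (a cascaded low-pass × high-pass product
does not have this property at these narrow bands). The zero-mean filtered
deviation is added back onto the original mean luminance; the filter itself
does not clip, so applying it twice equals one pass of the squared response
(a test invariant) — clipping to [0, 1] happens at movie composition.

**Mixture convention.** Frame t is the convex mixture
`s(t)·signal_c + (1 − s(t))·noise`, with `signal_c` the word whose deviation
from mean luminance is scaled by contrast (in % of the full deviation).
The convex form keeps luminance bounded and makes s = 0 (pure noise)
interpretable exactly. Noise is i.i.d. U[0, 1] per pixel by default
(truncated Gaussian selectable): a flat-spectrum field with mean 0.5.

**Distractors.** 4AFC distractors are assigned once per word bank by a
two-pass heuristic over zero-lag normalized cross-correlations of the
mean-subtracted unfiltered word images: a greedy pass maximizes
target–distractor similarity under the ≤ 6 reuse cap, then balancing sweeps
swap single distractors toward the median summed similarity, evening out
trial difficulty across targets.

## Experiment simulation

The default schedule is 4 sessions × 4 blocks × 200 trials from a 400-word
bank; each word appears 8 times, twice per condition. The builder assigns
each word's 8 (condition) tokens greedily to the blocks where it appears
least, breaking ties by block load and then randomly; with ≥ 8 blocks this
yields zero within-block repeats and exactly balanced blocks, and with
fewer blocks (reduced desk-scale geometries) repeats are spread as evenly
as possible. The validator re-checks every invariant by enumeration.

The staircase is evaluated after every trial once 20 experimental trials
have elapsed, for the condition of the trial just completed, and only when
that condition has ≥ 10 trials: accuracy over its last 10 trials above 50%
lowers that condition's contrast by the current step, below 50% raises it,
and an exact 5/10 tie changes nothing (the rule is stated only for strict
above/below). The adjustment uses the pre-reversal step; every direction
reversal then halves the step, floored at 1%. Contrast is clamped to
[1, 100] %; state persists across blocks and sessions.

## Synthetic observer

`P(correct) = 1/4 + (3/4 − λ)·σ(β(drive − θ))` with
`drive = c/100 · (⟨k_time, s⟩ + ⟨k_tf, W(s)⟩)`. Defaults: slope β = 8,
criterion θ = 1, lapse λ = 0.02. The logistic link is a convenience (any
monotone link would do) that gives closed-form checks, e.g. p = 0.625 at
zero drive with θ = 0, λ = 0.

The packaged default observer (`make_paperlike_observer`) has Gaussian-bump kernels with a
fine-to-coarse layout: temporal peaks at frames 3 / 7 / 18 / 13 for
conditions 4 / 3 / 2 / 1 (highest spatial frequencies earliest), and
time–frequency bumps at distinct oscillation frequencies (50 / 35 / 20 /
10 Hz) at the same epochs. Two calibrations are performed once, numerically,
on 256 seeded SNR draws:

- the tf kernel is scaled so its mean drive contribution is half the
  temporal kernel's (`tf_weight = 0.5`). Both CI domains then carry
  recoverable structure, while the temporal term dominates the time-domain
  CI — a stronger tf term visibly distorts time-domain CI shapes near the
  display edges (the oscillation-power covariance with s(t) is asymmetric
  under zero-padding);
- per-condition gains are set so mean P(correct) is 50% at target contrasts
  of 18.5 / 12.4 / 13.1 / 18.1 %, so the staircase settles higher for the
  extreme spatial-frequency bands than the intermediate ones.

The slope β = 8 makes the observer strongly stimulus-driven (trial-to-trial
SD of P(correct) ≈ 0.21): the per-trial response must carry enough
information about the sampling function for CIs to be recoverable at
realistic trial counts; a shallower observer mostly guesses identically on
every trial and no analysis could recover its kernels. Simulated cohorts add
smooth multiplicative kernel jitter (10% of the peak weight, Gaussian
smoothed) per participant for between-subject variability.

## Classification images

The raw CI is the difference of class means of the per-trial quantity
(the SNR vector, or its 11 × 24 Morlet power map): "weighted subtraction"
is read as weighting each trial by the inverse of its class count. A
count-weighted pooled difference is available via `weighting="pooled"`.

**Morlet analysis.** Three-cycle complex Morlet wavelets
(`σ_t = 3/(2πf)`, unit L2 norm, Gaussian envelope truncated at ±4σ_t) at
5–55 Hz in 5 Hz steps; power is the squared magnitude of the zero-padded
convolution. With only 24 samples no cone-of-influence masking is applied;
edge columns are attenuated and tests therefore probe interior columns.

**Bootstrap Z.** The null resamples trials with replacement while randomly
permuting correct/error labels (class counts preserved), recomputing the CI
each time (default 1000 resamples); Z = (raw − null mean)/null SD per cell.
Under an uninformative observer the Z values calibrate to mean ≈ 0, SD ≈ 1
(a test).

**Order of operations.** raw CI → bootstrap Z per participant → average
across participants → Gaussian smoothing → Pixel test. FWHMs: 19.6 ms
(time-domain); 29.3 ms × 17.7 Hz (time–frequency); σ = FWHM/(2√(2 ln 2)) in
cell units (frame = 8.33 ms, row = 5 Hz), reflective boundaries, unit-sum
kernel.

**Pixel test.** Implemented as a max-statistic permutation test rather than
a random-field-theory threshold: correct/error labels are permuted (pure
permutation, no resampling, so observed and null maps are exchangeable
under H0), each permuted CI is z-scored with the participant's bootstrap
null moments, null maps are averaged across participants with aligned
permutation indices and smoothed identically, and the two-tailed threshold
is the ⌈(1 − α)(P + 1)⌉-th order statistic of the per-permutation max |Z|.
Empirical familywise error over 500 null experiments is ≈ 0.05–0.06
(acceptance test band [0.03, 0.08]). Result metadata records the
smoothing; thresholds are symmetric about zero by construction.

## Signature classifier

**Fourier feature grid.** A 24-sample series is recoded as a 12 × 12 grid:
frequencies 5–60 Hz in 5 Hz steps (the 12 non-DC DFT bins, Nyquist
included) × twelve 30° phase bins covering [−180°, 180°). Each frequency's
Parseval power share lands in the bin containing its phase, so the grid sum
equals the series' non-DC mean-square power exactly. This 12 × 12 geometry
is the only one consistent with the representation sizes 144 and
1584 = 11 × 144.

**Representations.** time (24), Fourier of time (144), time–frequency
(264), Fourier of time–frequency (one grid per oscillation row, 1584).
Column order is row-major, oscillation-frequency-major.

**Ranking.** Discrimination index D = population variance of the condition
means ÷ pooled within-condition variance (SSw/(N − k)), per feature;
descending, ties to the lower column index; zero-within/nonzero-between is
an infinite sentinel ranked first. D is invariant to shifting a column and
to scaling it.

**Stepwise LOO SVM.** At step k the top-k features go to a linear SVM
(C = 1, features z-scored on each training fold); leave-one-out over
individual CIs; stop at ≥ 90% accuracy or feature exhaustion. The default
ranks once on the full matrix (the procedure as usually described);
`rank_in_fold=True` recomputes the ranking inside each training fold to
avoid selection leakage — the default's LOO accuracy is therefore an
optimistic estimate, which is acceptable here because the quantity of
interest is the relative classifiability of representations, not an
unbiased error rate. Exact one-sided binomial tails test accuracy against
the 25% 4AFC chance level.

**Signatures.** For each selected feature and condition,
`sign(m_c − m̄) · (m_c − m̄)² / error variance`, normalized by the global
max |·| to [−1, 1] (the squared statistic is non-negative; the sign of the
mean deviation is re-attached so the illustrated scale is two-sided),
display contrast `0.3 + 0.7·|value|`, exact zeros flagged omitted.

## Problem sizes

Defaults in tests and the acceptance script are chosen as desk-scale
simulations that preserve the structure of the full design: staircase runs
use 16 participants × 100 words × 4 sessions × 2 blocks × 100 trials
(800 per participant, contract-preserving); kernel recovery uses 800 trials
per condition; the classifier cohort is 16 participants × 150 trials per
condition (64 CIs); FWER calibration uses 500 null experiments of 120
trials with 400 bootstrap and 600 permutation resamples. The full 3200-trial
schedule is built and validated as such; only the response simulation is
scaled down.

## Known limitations

- The synthetic observer is a static template model: no learning, sequential
  dependencies, response times, or attention lapses beyond a constant lapse
  rate. Passing recovery tests shows the analysis chain is correct, not that
  human data would behave this way.
- The 24-sample Morlet decomposition has severe edge attenuation at low
  frequencies (a 5 Hz three-cycle wavelet is longer than the display); CI
  structure in the lowest rows and outer columns is correspondingly
  unreliable.
- LOO accuracy with a globally computed ranking is optimistically biased
  (see above); use `rank_in_fold=True` for unbiased estimates.
- The Pixel test is a permutation max-statistic implementation; a
  random-field-theory mode is not provided in this version.
- The distractor heuristic optimizes the stated objectives greedily; it is
  not an exact optimizer, and ships with similarity computed on unfiltered
  word images at zero lag.
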