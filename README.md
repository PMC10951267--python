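# temposample

Random temporal sampling psychophysics, simulated end to end: stimulus
generation, an adaptive 4AFC word-in-noise experiment, classification-image
recovery, and spatial-frequency signature classification.

## The problem

In the random temporal sampling paradigm a target word is shown for 200 ms
as 24 frames at 120 Hz. Each frame mixes a spatially bandpass-filtered word
with a white-noise field, and the signal-to-noise ratio s(t) oscillates
randomly within the trial — a sum of 5–55 Hz sinusoids with random
amplitudes and phases, normalized to [0, 0.75]. Because target visibility
fluctuates unpredictably in time, correlating the per-frame SNR with
response correctness yields a **classification image** (CI): a time-resolved
map of when (and, after a Morlet decomposition, at which SNR-oscillation
frequencies) stimulus information drives recognition. Four spatial-frequency
conditions (Butterworth bandpass, centers 1.2 / 2.4 / 4.8 / 9.6 cpd) make it
possible to ask whether word recognition proceeds coarse-to-fine or
fine-to-coarse.

Raw human data for this paradigm are not openly deposited, so the package is
built around a **synthetic observer**: a generative model whose correctness
probability on each trial is

```
drive = c/100 · ( ⟨k_time, s⟩ + ⟨k_tf, W(s)⟩ )
P(correct) = 1/4 + (3/4 − λ) · σ( β (drive − θ) )
```

with contrast c, temporal kernel k_time (per frame), time–frequency kernel
k_tf (per 5–55 Hz Morlet cell), power map W(s), logistic σ, slope β, lapse
λ, and criterion θ. The kernels are the ground truth that the analysis chain
must recover, which turns every stage of the pipeline into a testable
recovery problem.

## What the package provides

- `temposample.stimuli` — SNR sampling functions, word rendering, radial
  Butterworth bandpass filtering in cycles/degree, noise fields, stimulus
  movies, and the image-similarity-based 4AFC distractor assignment.
- `temposample.experiment` — trial schedules (3200 trials = 4 sessions × 4
  blocks × 200 at defaults; every word 8×, twice per condition, never twice
  in a block), the per-condition contrast staircase (start 35%, step 16%
  halved at each reversal, floor 1%, 50% accuracy target), and the simulated
  experiment loop.
- `temposample.observer` — the synthetic observer and its calibrated
  default with a fine-to-coarse kernel layout.
- `temposample.ci` — time-domain (1×24) and time–frequency (11×24) CIs,
  bootstrap Z-scoring, Gaussian smoothing (19.6 ms FWHM; 29.3 ms × 17.7 Hz),
  and a max-statistic permutation Pixel test (two-tailed, familywise
  α = 0.05).
- `temposample.classify` — the four CI feature spaces (24 / 144 / 264 /
  1584 features), discrimination-index ranking, stepwise linear-SVM
  classification with leave-one-out cross-validation, exact binomial tests
  against 25% chance, and condition signature maps.
- `temposample.pipeline` / `temposample.cli` — an end-to-end driver and a
  thin `temposample` command (`simulate`, `ci`, `classify`, `report`,
  `demo`).

## Worked example

`examples/` holds one short script per capability. Running
`python examples/05_signature_classifier.py` simulates 16 participants
(150 trials per condition each), computes their 64 individual Z-scored CIs,
and classifies them by spatial-frequency condition:

```
time       :   24 features available; best LOO accuracy 85.9% with 10 features (binomial p vs 25% chance = 1.7e-24)
tf_fourier : 1584 features available; best LOO accuracy 90.6% with 404 features (binomial p vs 25% chance = 1.7e-28)
signature map: 4 conditions x 404 features, values in [-0.24, 1.00], display contrast floor 0.30
```

Both representations classify far above the 25% chance level of a 4-class
problem, and the Fourier recoding of the time–frequency CIs — phase × power
grids per oscillation frequency — is the most classifiable, mirroring the
qualitative ordering the paradigm is known for. The signature map scores how
far each condition's mean sits from the grand mean (in error-variance
units, sign re-attached, normalized to [−1, 1]).

`python examples/03_classification_images.py` shows the recovery side: a
group CI whose Pixel-test-significant frames cluster on the generating
kernel's peak:

```
ground-truth kernel peak: frame 3 (25 ms)
recovered group Z-CI peak: frame 3
Pixel-test threshold: ±0.88 Z
significant frames: [0, 1, 2, 3, 4, 5, 6, 7]
```

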