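"""Parametric synthetic observer for the 4AFC word-in-noise task.

The observer turns a trial's SNR sampling function into a probability of a
correct response through condition-specific sensitivity kernels: a temporal
kernel (weight per display frame) and a time-frequency kernel (weight per
oscillation-frequency x frame cell of the Morlet power map). The internal
"drive" is scaled by target contrast and passed through a logistic
psychometric function with a 25% guessing floor and a lapse rate:

    drive = contrast/100 * ( <time_kernel, snr> + <tf_kernel, W(snr)> )
    p     = 1/4 + (3/4 - lapse) * logistic(slope * (drive - criterion))

The kernels are the ground truth that the classification-image pipeline is
expected to recover, and the condition-specific structure is what the
signature classifier is expected to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .ci import MORLET_FREQS, morlet_tf_power
from .stimuli import N_FRAMES, generate_snr_batch

__all__ = [
    "ObserverModel",
    "observer_p_correct",
    "observer_p_correct_batch",
    "sample_response",
    "make_paperlike_observer",
    "jitter_observer",
]

GUESS_RATE = 0.25
#: Contrast levels (%, per condition 1..4) around which the default observer
#: is calibrated to perform at 50% correct; extreme spatial-frequency bands
#: need more contrast than the intermediate ones.
DEFAULT_TARGET_CONTRASTS = (18.5, 12.4, 13.1, 18.1)


@dataclass(frozen=True)
class ObserverModel:
    """Condition-indexed sensitivity kernels plus psychometric parameters."""

    time_kernel: dict  # condition -> (24,) weights
    tf_kernel: dict  # condition -> (11, 24) weights
    slope: float = 8.0
    criterion: float = 1.0
    guess_rate: float = GUESS_RATE
    lapse: float = 0.02
    seed: int | None = None
    peak_table: dict = field(default_factory=dict)  # ground-truth peak metadata

    def __post_init__(self) -> None:
        if self.guess_rate != 0.25:
            raise ValueError("4AFC guessing floor must be 0.25")
        if not (0.0 <= self.lapse <= 0.1):
            raise ValueError("lapse must lie in [0, 0.1]")
        for c in self.time_kernel:
            if not (np.all(np.isfinite(self.time_kernel[c]))
                    and np.all(np.isfinite(self.tf_kernel[c]))):
                raise ValueError(f"non-finite kernel for condition {c}")

    def to_json(self, path) -> None:
        blob = {
            "slope": self.slope, "criterion": self.criterion,
            "guess_rate": self.guess_rate, "lapse": self.lapse, "seed": self.seed,
            "time_kernel": {str(c): np.asarray(k).tolist() for c, k in self.time_kernel.items()},
            "tf_kernel": {str(c): np.asarray(k).tolist() for c, k in self.tf_kernel.items()},
            "peak_table": self.peak_table,
        }
        with open(path, "w") as fh:
            json.dump(blob, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ObserverModel":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(
            time_kernel={int(c): np.asarray(k) for c, k in blob["time_kernel"].items()},
            tf_kernel={int(c): np.asarray(k) for c, k in blob["tf_kernel"].items()},
            slope=blob["slope"], criterion=blob["criterion"],
            guess_rate=blob["guess_rate"], lapse=blob["lapse"], seed=blob["seed"],
            peak_table={k: tuple(v) if isinstance(v, list) else v
                        for k, v in blob.get("peak_table", {}).items()},
        )


def _drive_batch(model: ObserverModel, condition: int, snr_matrix: np.ndarray,
                 contrast: float) -> np.ndarray:
    tk = np.asarray(model.time_kernel[condition], dtype=float)
    tfk = np.asarray(model.tf_kernel[condition], dtype=float)
    X = np.atleast_2d(np.asarray(snr_matrix, dtype=float))
    drive = X @ tk
    if np.any(tfk):
        P = morlet_tf_power(X)  # (n, 11, 24)
        drive = drive + P.reshape(len(P), -1) @ tfk.reshape(-1)
    return (contrast / 100.0) * drive


def observer_p_correct(model: ObserverModel, condition: int, snr, contrast: float) -> float:
    """Probability of a correct 4AFC response on one trial."""
    if condition not in model.time_kernel:
        raise KeyError(f"condition {condition} not defined for this observer")
    x = np.asarray(getattr(snr, "values", snr), dtype=float)
    return float(observer_p_correct_batch(model, condition, x[None, :], contrast)[0])


def observer_p_correct_batch(
    model: ObserverModel, condition: int, snr_matrix: np.ndarray, contrast: float
) -> np.ndarray:
    """Vectorized :func:`observer_p_correct` over an (n, 24) batch."""
    drive = _drive_batch(model, condition, snr_matrix, contrast)
    return model.guess_rate + (1.0 - model.guess_rate - model.lapse) * expit(
        model.slope * (drive - model.criterion)
    )


def sample_response(p: float, seed) -> bool:
    """Bernoulli draw of trial correctness; ``seed`` may be an int or a Generator."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability out of range: {p}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return bool(rng.random() < p)


def _gauss_bump(n: int, center: float, sigma: float) -> np.ndarray:
    x = np.arange(n, dtype=float)
    return np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def make_paperlike_observer(
    seed: int = 0,
    target_contrasts=DEFAULT_TARGET_CONTRASTS,
    slope: float = 8.0,
    criterion: float = 1.0,
    lapse: float = 0.02,
    tf_weight: float = 0.5,
    n_calibration: int = 256,
) -> ObserverModel:
    """Build the default four-condition observer with a fine-to-coarse profile.

    Temporal kernels are Gaussian bumps whose peak frame moves later as the
    spatial-frequency band gets lower (condition 4 peaks early, condition 1
    late), and each condition's time-frequency kernel concentrates on a
    distinct oscillation frequency at the same epoch. Kernel gains are
    calibrated numerically (on ``n_calibration`` seeded SNR draws) so that
    the mean response probability is 50% at each condition's target contrast,
    which places the staircase's steady state near those contrasts — higher
    for the extreme bands than for the intermediate ones. The kernel peak
    locations are recorded in ``peak_table`` as the ground truth for
    recovery tests.
    """
    # (time peak frame, tf oscillation row index, tf peak frame) per condition
    peaks = {1: (13, 1, 13), 2: (18, 3, 18), 3: (7, 6, 7), 4: (3, 9, 3)}
    d50 = criterion + logit((0.5 - GUESS_RATE) / (1.0 - GUESS_RATE - lapse)) / slope
    S = generate_snr_batch(seed=np.random.SeedSequence((seed, 915)).generate_state(1)[0] % 2**31,
                           n=n_calibration)
    Pmaps = morlet_tf_power(S).reshape(n_calibration, -1)
    time_kernel, tf_kernel, table = {}, {}, {}
    for c, (pt, row, col) in enumerate(peaks.values(), start=1):
        tk = _gauss_bump(N_FRAMES, pt, 2.0)
        tfk = np.outer(_gauss_bump(11, row, 1.0), _gauss_bump(N_FRAMES, col, 2.0))
        m_time = float(np.mean(S @ tk))
        m_tf = float(np.mean(Pmaps @ tfk.reshape(-1)))
        tfk = tfk * (tf_weight * m_time / m_tf)  # equalize the two drive terms
        gain = d50 / ((target_contrasts[c - 1] / 100.0) * (m_time * (1.0 + tf_weight)))
        time_kernel[c] = gain * tk
        tf_kernel[c] = gain * tfk
        table[c] = {
            "time_peak_frame": pt,
            "tf_peak_freq_hz": float(MORLET_FREQS[row]),
            "tf_peak_frame": col,
            "target_contrast_pct": float(target_contrasts[c - 1]),
        }
    return ObserverModel(
        time_kernel=time_kernel, tf_kernel=tf_kernel, slope=slope,
        criterion=criterion, lapse=lapse, seed=seed, peak_table=table,
    )


def jitter_observer(model: ObserverModel, seed: int, amount: float = 0.1) -> ObserverModel:
    """Participant-level variant: kernels perturbed by smooth Gaussian noise.

    ``amount`` scales the perturbation relative to each kernel's peak weight;
    used to give simulated cohorts realistic between-participant variability
    while preserving the condition-specific structure.
    """
    rng = np.random.default_rng(seed)
    tks, tfks = {}, {}
    for c in model.time_kernel:
        tk = np.asarray(model.time_kernel[c], dtype=float)
        tfk = np.asarray(model.tf_kernel[c], dtype=float)
        tks[c] = tk + gaussian_filter(rng.normal(size=tk.shape), 1.5) * amount * np.abs(tk).max()
        tfks[c] = tfk + gaussian_filter(rng.normal(size=tfk.shape), 1.0) * amount * np.abs(tfk).max()
    return replace(model, time_kernel=tks, tf_kernel=tfks, seed=seed)
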