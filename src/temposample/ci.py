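"""Classification-image pipeline.

From a set of trials — each carrying a 24-sample SNR sampling function and a
binary correctness — this module computes classification images (CIs) of
processing efficiency in the time domain (1 x 24) and in the time-frequency
domain (11 x 24, oscillation frequencies 5..55 Hz via three-cycle complex
Morlet wavelets), transforms them to Z scores by a bootstrap null, averages
across participants, smooths with Gaussian kernels of fixed FWHM, and marks
significant cells with a familywise-error-controlling Pixel test realized as
a max-statistic permutation test.

The processing order is: raw CI -> bootstrap Z (per participant) -> average
across participants -> smooth -> Pixel test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .stimuli import FRAME_RATE, N_FRAMES, SNR_FREQS

__all__ = [
    "RawCI",
    "ZCI",
    "PixelTestResult",
    "MORLET_FREQS",
    "FWHM_TO_SIGMA",
    "DEFAULT_FWHM_TIME_MS",
    "DEFAULT_FWHM_TF_TIME_MS",
    "DEFAULT_FWHM_TF_FREQ_HZ",
    "morlet_bank",
    "morlet_tf_power",
    "compute_time_ci",
    "compute_tf_ci",
    "bootstrap_z",
    "smooth_ci",
    "average_z",
    "permutation_null_z",
    "pixel_test",
    "group_pixel_analysis",
]

#: Morlet analysis frequencies, Hz (11 rows of the time-frequency CI).
MORLET_FREQS = np.asarray(SNR_FREQS, dtype=float)
N_CYCLES = 3.0
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548
FRAME_MS = 1000.0 / FRAME_RATE
FREQ_STEP_HZ = 5.0

# Gaussian smoothing defaults (full width at half maximum).
DEFAULT_FWHM_TIME_MS = 19.6
DEFAULT_FWHM_TF_TIME_MS = 29.3
DEFAULT_FWHM_TF_FREQ_HZ = 17.7


@dataclass(frozen=True)
class RawCI:
    """Raw classification image: difference of class-mean stimulus profiles."""

    domain: str  # "time" or "time_frequency"
    values: np.ndarray  # (24,) or (11, 24)
    n_correct: int
    n_error: int
    participant_id: int | str | None = None
    condition: int | None = None


@dataclass(frozen=True)
class ZCI:
    """Z-scored CI with bootstrap provenance and smoothing metadata."""

    domain: str
    values: np.ndarray
    n_boot: int
    smoothing: dict | None = None  # e.g. {"fwhm_time_ms": 19.6}
    participant_id: int | str | None = None
    condition: int | None = None
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None


@dataclass(frozen=True)
class PixelTestResult:
    """Two-tailed max-statistic significance thresholds and mask."""

    z_threshold_high: float
    z_threshold_low: float
    significance_mask: np.ndarray
    alpha: float
    search_space: int
    smoothness: dict


# --------------------------------------------------------------------------
# Morlet time-frequency analysis


def _morlet_wavelet(freq: float, frame_rate: float = FRAME_RATE) -> np.ndarray:
    """Three-cycle complex Morlet at ``freq`` Hz, unit-energy, on the frame grid."""
    sigma_t = N_CYCLES / (2.0 * np.pi * freq)
    half = int(np.ceil(4.0 * sigma_t * frame_rate))
    t = np.arange(-half, half + 1) / frame_rate
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return w / np.linalg.norm(w)


def morlet_bank(
    n_frames: int = N_FRAMES,
    freqs: Sequence[float] = tuple(MORLET_FREQS),
    frame_rate: float = FRAME_RATE,
) -> np.ndarray:
    """Complex bank B with shape (n_freqs, n_frames, n_frames).

    ``B[f, tau] @ x`` is the zero-padded convolution of ``x`` with the
    conjugate Morlet at frequency ``f`` evaluated at frame ``tau``, so
    ``|B @ x|**2`` is the full time-frequency power map.
    """
    bank = np.zeros((len(freqs), n_frames, n_frames), dtype=complex)
    for fi, f in enumerate(freqs):
        w = np.conj(_morlet_wavelet(f, frame_rate))
        half = (len(w) - 1) // 2
        for tau in range(n_frames):
            for k in range(-half, half + 1):
                t = tau + k
                if 0 <= t < n_frames:
                    bank[fi, tau, t] += w[k + half]
    return bank


_BANK_CACHE: dict[tuple, np.ndarray] = {}


def _bank(n_frames: int = N_FRAMES) -> np.ndarray:
    key = (n_frames, tuple(MORLET_FREQS))
    if key not in _BANK_CACHE:
        _BANK_CACHE[key] = morlet_bank(n_frames)
    return _BANK_CACHE[key]


def morlet_tf_power(snr) -> np.ndarray:
    """Time-frequency power map (11 x 24) of a sampling function.

    Squared magnitude of the complex Morlet convolution at each frequency
    (5..55 Hz, 5 Hz steps) and frame; edges are zero-padded (no
    cone-of-influence masking — the series is only 200 ms long).
    Accepts a :class:`~temposample.stimuli.SamplingFunction` or a plain
    vector; also accepts a (n, 24) batch, returning (n, 11, 24).
    """
    x = np.asarray(getattr(snr, "values", snr), dtype=float)
    if x.ndim == 1:
        return np.abs(np.einsum("fst,t->fs", _bank(x.shape[-1]), x)) ** 2
    return np.abs(np.einsum("fst,nt->nfs", _bank(x.shape[-1]), x)) ** 2


# --------------------------------------------------------------------------
# Raw classification images


def _class_mean_difference(
    X: np.ndarray, correct: np.ndarray, weighting: str = "class_mean"
) -> np.ndarray:
    correct = np.asarray(correct, dtype=bool)
    if weighting == "class_mean":
        return X[correct].mean(axis=0) - X[~correct].mean(axis=0)
    if weighting == "pooled":
        # count-weighted: signed sum over trials divided by the total count
        sign = np.where(correct, 1.0, -1.0)
        return np.tensordot(sign, X, axes=1) / len(correct)
    raise ValueError(f"unknown weighting {weighting!r}")


def _check_classes(correct: np.ndarray) -> None:
    correct = np.asarray(correct, dtype=bool)
    if not correct.any():
        raise ValueError("no correct trials: cannot form the correct-class mean")
    if correct.all():
        raise ValueError("no error trials: cannot form the error-class mean")


def compute_time_ci(
    snr_matrix: np.ndarray,
    correct: np.ndarray,
    participant_id=None,
    condition=None,
    weighting: str = "class_mean",
) -> RawCI:
    """Time-domain CI: mean SNR profile of correct minus error trials.

    ``snr_matrix`` is (n_trials, 24). The default "weighted subtraction"
    weights each trial by the inverse of its class count (i.e. a difference
    of class means); ``weighting="pooled"`` divides by the total trial count
    instead.
    """
    X = np.atleast_2d(np.asarray(snr_matrix, dtype=float))
    _check_classes(correct)
    values = _class_mean_difference(X, correct, weighting)
    c = int(np.sum(correct))
    return RawCI("time", values, c, X.shape[0] - c, participant_id, condition)


def compute_tf_ci(
    snr_matrix: np.ndarray,
    correct: np.ndarray,
    participant_id=None,
    condition=None,
    weighting: str = "class_mean",
) -> RawCI:
    """Time-frequency CI: class-mean difference of Morlet power maps (11 x 24)."""
    X = np.atleast_2d(np.asarray(snr_matrix, dtype=float))
    _check_classes(correct)
    P = morlet_tf_power(X)  # (n, 11, 24)
    values = _class_mean_difference(P.reshape(len(P), -1), correct, weighting)
    c = int(np.sum(correct))
    return RawCI(
        "time_frequency", values.reshape(P.shape[1:]), c, X.shape[0] - c,
        participant_id, condition,
    )


def _feature_stack(snr_matrix: np.ndarray, domain: str) -> np.ndarray:
    """Per-trial cell values: (n, cells) for the requested CI domain."""
    X = np.atleast_2d(np.asarray(snr_matrix, dtype=float))
    if domain == "time":
        return X
    if domain == "time_frequency":
        P = morlet_tf_power(X)
        return P.reshape(len(P), -1)
    raise ValueError(f"unknown domain {domain!r}")


# --------------------------------------------------------------------------
# Bootstrap Z-scoring


def bootstrap_z(
    raw: RawCI,
    snr_matrix: np.ndarray,
    correct: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    weighting: str = "class_mean",
) -> ZCI:
    """Transform a raw CI to Z scores against a bootstrap null.

    The null resamples trials with replacement while randomly permuting the
    correct/error labels (class counts preserved), recomputing the CI per
    resample; Z is (raw - null mean) / null SD elementwise.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    F = _feature_stack(snr_matrix, raw.domain)
    n = F.shape[0]
    nc = raw.n_correct
    rng = np.random.default_rng(seed)
    # Resampled + label-permuted CI as a weight matrix applied to the trials:
    # drawing nc and (n - nc) trials with replacement from the pool and
    # differencing their means.
    W = np.zeros((n_boot, n))
    for b in range(n_boot):
        W[b] = np.bincount(rng.integers(0, n, nc), minlength=n) / nc
        W[b] -= np.bincount(rng.integers(0, n, n - nc), minlength=n) / (n - nc)
    null = W @ F  # (n_boot, cells)
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    scale = max(float(np.abs(F).max()), np.finfo(float).tiny)
    if np.any(sd <= 1e-12 * scale):
        raise ValueError("degenerate bootstrap null: zero SD at some cell")
    flat = raw.values.reshape(-1)
    z = ((flat - mu) / sd).reshape(raw.values.shape)
    return ZCI(
        domain=raw.domain, values=z, n_boot=n_boot, smoothing=None,
        participant_id=raw.participant_id, condition=raw.condition,
        null_mean=mu.reshape(raw.values.shape), null_sd=sd.reshape(raw.values.shape),
    )


# --------------------------------------------------------------------------
# Smoothing, averaging, Pixel test


def _sigma_cells(domain: str, fwhm_time_ms: float, fwhm_freq_hz: float | None):
    st = fwhm_time_ms / FWHM_TO_SIGMA / FRAME_MS
    if domain == "time":
        return (st,)
    if fwhm_freq_hz is None:
        raise ValueError("time-frequency smoothing needs fwhm_freq_hz")
    return (fwhm_freq_hz / FWHM_TO_SIGMA / FREQ_STEP_HZ, st)


def smooth_ci(
    z: ZCI,
    fwhm_time_ms: float | None = None,
    fwhm_freq_hz: float | None = None,
) -> ZCI:
    """Gaussian-smooth a Z-scored CI (unit-sum kernel, reflective edges).

    Defaults: 19.6 ms FWHM for time-domain CIs; 29.3 ms x 17.7 Hz for
    time-frequency CIs. sigma = FWHM / (2 sqrt(2 ln 2)), converted to cell
    units (one frame = 8.33 ms, one row = 5 Hz).
    """
    if fwhm_time_ms is None:
        fwhm_time_ms = (
            DEFAULT_FWHM_TIME_MS if z.domain == "time" else DEFAULT_FWHM_TF_TIME_MS
        )
    if fwhm_freq_hz is None and z.domain == "time_frequency":
        fwhm_freq_hz = DEFAULT_FWHM_TF_FREQ_HZ
    if fwhm_time_ms <= 0 or (fwhm_freq_hz is not None and fwhm_freq_hz <= 0):
        raise ValueError("FWHMs must be positive")
    sigma = _sigma_cells(z.domain, fwhm_time_ms, fwhm_freq_hz)
    values = ndimage.gaussian_filter(z.values, sigma=sigma, mode="reflect")
    meta = {"fwhm_time_ms": fwhm_time_ms}
    if z.domain == "time_frequency":
        meta["fwhm_freq_hz"] = fwhm_freq_hz
    return replace(z, values=values, smoothing=meta)


def average_z(zcis: Sequence[ZCI]) -> ZCI:
    """Average Z-scored CIs across participants (same domain and shape)."""
    if not zcis:
        raise ValueError("no ZCIs to average")
    domains = {z.domain for z in zcis}
    if len(domains) != 1:
        raise ValueError(f"mixed domains {domains}")
    values = np.mean([z.values for z in zcis], axis=0)
    return ZCI(
        domain=zcis[0].domain, values=values,
        n_boot=min(z.n_boot for z in zcis),
        smoothing=zcis[0].smoothing, condition=zcis[0].condition,
    )


def permutation_null_z(
    zci: ZCI,
    snr_matrix: np.ndarray,
    correct: np.ndarray,
    n_perm: int,
    seed: int,
    weighting: str = "class_mean",
) -> np.ndarray:
    """Label-permutation null CIs, Z-scored with the bootstrap null moments.

    Returns (n_perm, *shape). Pure permutation (no resampling) keeps the
    observed map exchangeable with the null maps under H0, which is what
    gives the Pixel test its familywise error control.
    """
    if zci.null_mean is None or zci.null_sd is None:
        raise ValueError("ZCI lacks bootstrap null moments; run bootstrap_z first")
    F = _feature_stack(snr_matrix, zci.domain)
    n = F.shape[0]
    nc = int(np.sum(np.asarray(correct, dtype=bool)))
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, F.shape[1]))
    chunk = max(1, int(2e7) // (n * F.shape[1]))
    for lo in range(0, n_perm, chunk):
        hi = min(lo + chunk, n_perm)
        perms = np.argsort(rng.random((hi - lo, n)), axis=1)
        null[lo:hi] = F[perms[:, :nc]].mean(axis=1) - F[perms[:, nc:]].mean(axis=1)
    mu = zci.null_mean.reshape(-1)
    sd = zci.null_sd.reshape(-1)
    return ((null - mu) / sd).reshape((n_perm, *zci.values.shape))


def pixel_test(
    group_z: ZCI, null_maps: np.ndarray, alpha: float = 0.05
) -> PixelTestResult:
    """Two-way Pixel test: symmetric max-statistic thresholds at level alpha.

    ``null_maps`` is a stack of group-level smoothed null Z maps (one per
    label permutation, averaged over participants and smoothed exactly like
    the observed map). The threshold is the ceil((1 - alpha)(P + 1))-th order
    statistic of the per-permutation max |Z|; cells at or beyond +/-threshold
    in the observed map are flagged.
    """
    if group_z.smoothing is None:
        raise ValueError("Pixel test needs smoothing metadata; smooth the map first")
    null_maps = np.asarray(null_maps)
    if null_maps.shape[1:] != group_z.values.shape:
        raise ValueError("null map shape does not match the observed map")
    maxes = np.max(np.abs(null_maps.reshape(len(null_maps), -1)), axis=1)
    P = len(maxes)
    k = int(np.ceil((1.0 - alpha) * (P + 1))) - 1
    thr = float(np.sort(maxes)[min(k, P - 1)])
    mask = np.abs(group_z.values) >= thr
    return PixelTestResult(
        z_threshold_high=thr, z_threshold_low=-thr, significance_mask=mask,
        alpha=alpha, search_space=int(group_z.values.size),
        smoothness=dict(group_z.smoothing),
    )


def group_pixel_analysis(
    trials_by_participant: Sequence[tuple],
    domain: str = "time",
    n_boot: int = 1000,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    fwhm_time_ms: float | None = None,
    fwhm_freq_hz: float | None = None,
    condition: int | None = None,
) -> tuple[ZCI, PixelTestResult]:
    """Full group pipeline for one condition: raw -> Z -> average -> smooth -> Pixel.

    ``trials_by_participant`` is a sequence of ``(snr_matrix, correct)``
    pairs, one per participant. The permutation index is aligned across
    participants so each null replicate is a coherent group map.
    """
    ss = np.random.SeedSequence(seed)
    compute = compute_time_ci if domain == "time" else compute_tf_ci
    zs, nulls = [], []
    for pid, (X, corr) in enumerate(trials_by_participant):
        boot_seed, perm_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
        raw = compute(X, corr, participant_id=pid, condition=condition)
        z = bootstrap_z(raw, X, corr, n_boot=n_boot, seed=boot_seed)
        zs.append(z)
        nulls.append(permutation_null_z(z, X, corr, n_perm, seed=perm_seed))
    group = average_z(zs)
    group = smooth_ci(group, fwhm_time_ms=fwhm_time_ms, fwhm_freq_hz=fwhm_freq_hz)
    null_group = np.mean(nulls, axis=0)  # (P, *shape), aligned by permutation index
    sigma = _sigma_cells(group.domain, group.smoothing["fwhm_time_ms"],
                         group.smoothing.get("fwhm_freq_hz"))
    null_sm = ndimage.gaussian_filter(
        null_group, sigma=(0.0, *sigma), mode="reflect"
    )
    return group, pixel_test(group, null_sm, alpha=alpha)
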