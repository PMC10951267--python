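"""Stimulus generation for random temporal sampling experiments.

Everything on the stimulus side of the paradigm lives here: rendering of
five-letter word images, bandpass spatial-frequency filtering in cycles per
degree, white-noise fields, the random SNR sampling functions that modulate
target visibility over the 200 ms display, frame-sequence composition, and
the image-similarity-driven distractor assignment for the 4AFC task.

Conventions
-----------
Images are float arrays with luminance in [0, 1] and a ``px_per_deg`` scale.
A stimulus movie is 24 frames at 120 Hz; frame ``t`` is the convex mixture
``s(t) * signal + (1 - s(t)) * noise`` where ``s`` is the trial's SNR
sampling function (normalized to span [0, 0.75], so the noise never fully
disappears).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from matplotlib import font_manager
from PIL import Image, ImageDraw, ImageFont

__all__ = [
    "FilterSpec",
    "SamplingFunction",
    "LuminanceImage",
    "StimulusMovie",
    "DistractorMap",
    "GlyphSpec",
    "CONDITION_FILTERS",
    "generate_snr_function",
    "render_word_image",
    "butterworth_bandpass",
    "generate_noise_field",
    "compose_stimulus_movie",
    "select_distractors",
    "image_cross_correlation",
]

#: Frames per 200 ms display at the 120 Hz refresh rate.
N_FRAMES = 24
FRAME_RATE = 120.0
#: SNR oscillation components, Hz.
SNR_FREQS = tuple(range(5, 60, 5))
SNR_MAX = 0.75
#: Side of the square stimulation area, degrees of visual angle.
STIM_AREA_DEG = 8.9
WORD_WIDTH_DEG = 3.4
X_HEIGHT_DEG = 0.75


@dataclass(frozen=True)
class FilterSpec:
    """Radial Butterworth bandpass specification in cycles per degree.

    ``low_cut`` and ``high_cut`` are the half-power (gain^2 = 0.5) points;
    ``order`` controls roll-off steepness.
    """

    center_freq: float
    low_cut: float
    high_cut: float
    order: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.low_cut < self.center_freq < self.high_cut):
            raise ValueError(
                f"require 0 < low_cut < center_freq < high_cut, got "
                f"{self.low_cut}, {self.center_freq}, {self.high_cut}"
            )
        if self.order < 1:
            raise ValueError("filter order must be a positive integer")

    @property
    def cycles_per_letter(self) -> float:
        """Approximate object-frequency equivalent (cpl) of the center.

        Derived metadata: the conventional condition labels map 1.2/2.4/4.8/
        9.6 cpd to 1.7/3.5/7.1/14.1 cpl, i.e. an effective letter unit of
        about 1.47 deg for these word stimuli.
        """
        return self.center_freq * 1.47


#: The four spatial-frequency conditions: center (half-power band) in cpd.
CONDITION_FILTERS: Mapping[int, FilterSpec] = {
    1: FilterSpec(1.2, 0.9, 1.5),
    2: FilterSpec(2.4, 1.8, 3.0),
    3: FilterSpec(4.8, 3.6, 6.0),
    4: FilterSpec(9.6, 7.2, 12.0),
}


@dataclass(frozen=True)
class SamplingFunction:
    """Per-trial SNR trajectory over the 24 display frames.

    The pre-normalization waveform is a sum of sinusoids at 5..55 Hz in 5 Hz
    steps with random amplitudes and phases; normalization pins the minimum
    to 0 and the maximum to 0.75.
    """

    values: np.ndarray
    frame_rate: float = FRAME_RATE
    freq_components: tuple = SNR_FREQS
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class LuminanceImage:
    """2-D luminance array in [0, 1] with a pixels-per-degree scale."""

    pixels: np.ndarray
    px_per_deg: float = 32.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=float))

    @property
    def shape(self):
        return self.pixels.shape

    def to_png(self, path) -> None:
        """Write an 8-bit grayscale PNG for inspection."""
        arr = np.clip(self.pixels, 0.0, 1.0)
        Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


@dataclass(frozen=True)
class StimulusMovie:
    """24-frame sequence mixing a contrast-scaled signal with a noise field."""

    frames: tuple
    snr: SamplingFunction
    signal_id: str
    contrast: float


@dataclass(frozen=True)
class DistractorMap:
    """Per-target 4AFC distractor assignment.

    ``distractors`` maps each target word to exactly three other words;
    ``summed_similarity`` records the summed zero-lag image cross-correlation
    of the three distractors with their target.
    """

    distractors: Mapping[str, tuple]
    summed_similarity: Mapping[str, float]


# --------------------------------------------------------------------------
# SNR sampling functions


def generate_snr_function(
    seed: int,
    n_frames: int = N_FRAMES,
    frame_rate: float = FRAME_RATE,
    freqs: Sequence[float] = SNR_FREQS,
    snr_max: float = SNR_MAX,
) -> SamplingFunction:
    """Draw one random SNR sampling function.

    A sum of sinusoids at ``freqs`` with i.i.d. uniform amplitudes and phases
    is sampled on the frame grid and affinely rescaled so its minimum is 0
    and its maximum is ``snr_max``. Deterministic for a given seed.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / frame_rate
    for _ in range(16):
        amps = rng.uniform(0.0, 1.0, size=len(freqs))
        phases = rng.uniform(0.0, 2 * np.pi, size=len(freqs))
        wave = np.sum(
            amps[:, None] * np.sin(2 * np.pi * np.asarray(freqs)[:, None] * t + phases[:, None]),
            axis=0,
        )
        span = wave.max() - wave.min()
        if span > 1e-12:  # degenerate flat draw: re-draw from the same stream
            break
    values = (wave - wave.min()) / span * snr_max
    return SamplingFunction(values=values, frame_rate=frame_rate, freq_components=tuple(freqs), seed=seed)


def generate_snr_batch(
    seed: int,
    n: int,
    n_frames: int = N_FRAMES,
    frame_rate: float = FRAME_RATE,
    freqs: Sequence[float] = SNR_FREQS,
    snr_max: float = SNR_MAX,
) -> np.ndarray:
    """Vectorized draw of ``n`` sampling functions, as an (n, n_frames) array.

    Equivalent in distribution to ``n`` calls of :func:`generate_snr_function`
    with independent seeds; used where per-trial object overhead matters
    (null-calibration simulations).
    """
    rng = np.random.default_rng(seed)
    f = np.asarray(freqs, dtype=float)
    t = np.arange(n_frames) / frame_rate
    amps = rng.uniform(0.0, 1.0, size=(n, len(f)))
    phases = rng.uniform(0.0, 2 * np.pi, size=(n, len(f)))
    waves = np.einsum(
        "nf,nft->nt", amps, np.sin(2 * np.pi * f[None, :, None] * t[None, None, :] + phases[:, :, None])
    )
    lo = waves.min(axis=1, keepdims=True)
    span = waves.max(axis=1, keepdims=True) - lo
    span[span < 1e-12] = 1.0
    return (waves - lo) / span * snr_max


# --------------------------------------------------------------------------
# Word rendering


@dataclass(frozen=True)
class GlyphSpec:
    """Font configuration for word rendering.

    The packaged default is DejaVu Sans (a widely redistributable sans-serif);
    glyph metrics are normalized after rendering so the ink bounding box spans
    ``word_width_deg`` horizontally and lowercase x-height is
    ``x_height_deg``, matching the experiment's word geometry.
    """

    font_path: str = field(
        default_factory=lambda: font_manager.findfont("DejaVu Sans")
    )
    word_width_deg: float = WORD_WIDTH_DEG
    x_height_deg: float = X_HEIGHT_DEG
    base_size_px: int = 128


def _render_text_ink(text: str, font: ImageFont.FreeTypeFont) -> np.ndarray:
    """Render text black-on-white at the font's size; return the ink crop."""
    pad = font.size
    left, top, right, bottom = font.getbbox(text)
    w, h = right - left + 2 * pad, bottom - top + 2 * pad
    img = Image.new("L", (w, h), 255)
    ImageDraw.Draw(img).text((pad - left, pad - top), text, font=font, fill=0)
    arr = np.asarray(img, dtype=float) / 255.0
    ink = arr < 0.5
    if not ink.any():
        raise ValueError(f"text {text!r} produced no ink with font {font.path}")
    rows = np.where(ink.any(axis=1))[0]
    cols = np.where(ink.any(axis=0))[0]
    return arr[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def render_word_image(
    word: str,
    px_per_deg: float = 32.0,
    glyph_spec: GlyphSpec | None = None,
    area_deg: float = STIM_AREA_DEG,
) -> LuminanceImage:
    """Render a five-letter word, dark glyphs on a light field.

    The word is drawn with the configured font, cropped to its ink bounding
    box, rescaled so its width is 3.4 deg and the font's x-height is 0.75 deg,
    and centered on a uniform white square covering ``area_deg`` per side.
    Deterministic for a given glyph spec.
    """
    if len(word) != 5:
        raise ValueError(f"expected a 5-letter word, got {word!r} ({len(word)} letters)")
    if px_per_deg <= 0:
        raise ValueError("px_per_deg must be positive")
    spec = glyph_spec or GlyphSpec()
    font = ImageFont.truetype(spec.font_path, spec.base_size_px)
    for ch in word:
        if ch.isspace():
            raise ValueError(f"unrenderable character {ch!r} in {word!r}")
        l, t, r, b = font.getbbox(ch)
        if r <= l or b <= t:
            raise ValueError(f"unrenderable character {ch!r} in {word!r}")
    ink = _render_text_ink(word, font)
    x_ink = _render_text_ink("x", font)  # x-height reference at the same size
    target_w = spec.word_width_deg * px_per_deg
    target_h = ink.shape[0] * (spec.x_height_deg * px_per_deg / x_ink.shape[0])
    glyphs = np.asarray(
        Image.fromarray(np.round(ink * 255).astype(np.uint8), mode="L").resize(
            (max(1, round(target_w)), max(1, round(target_h))), Image.LANCZOS
        ),
        dtype=float,
    ) / 255.0
    side = round(area_deg * px_per_deg)
    canvas = np.ones((side, side), dtype=float)
    r0 = (side - glyphs.shape[0]) // 2
    c0 = (side - glyphs.shape[1]) // 2
    canvas[r0 : r0 + glyphs.shape[0], c0 : c0 + glyphs.shape[1]] = glyphs
    return LuminanceImage(pixels=np.clip(canvas, 0.0, 1.0), px_per_deg=px_per_deg)


# --------------------------------------------------------------------------
# Spatial-frequency filtering


def _radial_response(shape, px_per_deg: float, spec: FilterSpec) -> np.ndarray:
    """Butterworth bandpass gain on the 2-D FFT frequency grid (cpd)."""
    fy = np.fft.fftfreq(shape[0]) * px_per_deg
    fx = np.fft.fftfreq(shape[1]) * px_per_deg
    f = np.hypot(fy[:, None], fx[None, :])
    width = spec.high_cut - spec.low_cut
    f0sq = spec.low_cut * spec.high_cut
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (f * f - f0sq) / (f * width)
    u[f == 0] = np.inf  # DC is removed (and restored as the image mean)
    return 1.0 / np.sqrt(1.0 + u ** (2 * spec.order))


def butterworth_bandpass(
    image: LuminanceImage, spec: FilterSpec, clip: bool = False
) -> LuminanceImage:
    """Bandpass-filter an image radially in the spatial-frequency domain.

    The gain is ``|H(f)| = (1 + ((f^2 - f_l f_h) / (f W))^{2n})^{-1/2}`` with
    ``W = f_h - f_l``: exactly half power at both cutoffs, gain ~1 at the
    center frequency. The zero-mean filtered deviation is added back onto the
    original mean luminance; pass ``clip=True`` to clamp into [0, 1] (movie
    composition clips anyway).
    """
    nyquist = image.px_per_deg / 2.0
    if spec.high_cut >= nyquist:
        raise ValueError(
            f"high_cut {spec.high_cut} cpd >= image Nyquist {nyquist} cpd; "
            "increase px_per_deg"
        )
    mean = image.pixels.mean()
    dev = image.pixels - mean
    gain = _radial_response(image.pixels.shape, image.px_per_deg, spec)
    filtered = np.fft.ifft2(np.fft.fft2(dev) * gain).real + mean
    if clip:
        filtered = np.clip(filtered, 0.0, 1.0)
    return LuminanceImage(pixels=filtered, px_per_deg=image.px_per_deg)


# --------------------------------------------------------------------------
# Noise and movie composition


def generate_noise_field(
    shape, seed: int, px_per_deg: float = 32.0, distribution: str = "uniform"
) -> LuminanceImage:
    """Fresh white-noise field: independent pixel luminances, flat spectrum.

    ``distribution`` is ``"uniform"`` (U[0,1], the default) or ``"gaussian"``
    (N(0.5, 0.15) truncated to [0, 1]).
    """
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        pix = rng.uniform(0.0, 1.0, size=shape)
    elif distribution == "gaussian":
        pix = np.clip(rng.normal(0.5, 0.15, size=shape), 0.0, 1.0)
    else:
        raise ValueError(f"unknown noise distribution {distribution!r}")
    return LuminanceImage(pixels=pix, px_per_deg=px_per_deg)


def apply_contrast(signal: LuminanceImage, contrast: float) -> np.ndarray:
    """Scale the signal's deviation from mean luminance by ``contrast`` %."""
    if not (1.0 <= contrast <= 100.0):
        raise ValueError(f"contrast must be in [1, 100] %, got {contrast}")
    mean = signal.pixels.mean()
    return mean + (contrast / 100.0) * (signal.pixels - mean)


def compose_stimulus_movie(
    signal: LuminanceImage,
    noise: LuminanceImage,
    snr: SamplingFunction,
    contrast: float,
    signal_id: str = "",
) -> StimulusMovie:
    """Mix signal and noise frame by frame under the SNR trajectory.

    Frame ``t`` is ``s(t) * signal_c + (1 - s(t)) * noise`` with ``signal_c``
    the contrast-scaled signal; at ``s = 0`` the frame is pure noise. Frames
    are clipped to [0, 1].
    """
    if signal.pixels.shape != noise.pixels.shape:
        raise ValueError(
            f"signal shape {signal.pixels.shape} != noise shape {noise.pixels.shape}"
        )
    sig_c = apply_contrast(signal, contrast)
    frames = tuple(
        LuminanceImage(
            pixels=np.clip(s * sig_c + (1.0 - s) * noise.pixels, 0.0, 1.0),
            px_per_deg=signal.px_per_deg,
        )
        for s in snr.values
    )
    return StimulusMovie(frames=frames, snr=snr, signal_id=signal_id, contrast=contrast)


# --------------------------------------------------------------------------
# Distractor assignment


def image_cross_correlation(a: LuminanceImage, b: LuminanceImage) -> float:
    """Zero-lag normalized correlation of the mean-subtracted images."""
    x = a.pixels.ravel() - a.pixels.mean()
    y = b.pixels.ravel() - b.pixels.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        return 0.0
    return float(np.dot(x, y) / denom)


def select_distractors(
    image_bank: Mapping[str, LuminanceImage],
    max_reuse: int = 6,
    seed: int = 0,
    n_distractors: int = 3,
    balance_sweeps: int = 4,
) -> DistractorMap:
    """Assign three 4AFC distractors per target from the word bank.

    Two-pass heuristic over the zero-lag cross-correlation matrix of the
    (unfiltered) word images: pass 1 greedily gives each target its most
    similar available words, honoring the reuse cap (no word serves more than
    ``max_reuse`` distinct targets); pass 2 sweeps over targets swapping
    single distractors whenever that shrinks the across-target spread of
    summed similarity, keeping trial difficulty as even as possible.
    """
    words = sorted(image_bank)
    n = len(words)
    if n < n_distractors + 1:
        raise ValueError(f"need at least {n_distractors + 1} words, got {n}")
    if (n - 1) * max_reuse < n * n_distractors:
        raise ValueError(
            f"reuse cap {max_reuse} infeasible: {n} targets x {n_distractors} "
            f"slots exceed {(n - 1) * max_reuse} available uses"
        )
    rng = np.random.default_rng(seed)
    mats = np.stack([image_bank[w].pixels.ravel() for w in words])
    mats = mats - mats.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(mats, axis=1)
    norms[norms == 0] = 1.0
    sim = (mats @ mats.T) / np.outer(norms, norms)
    np.fill_diagonal(sim, -np.inf)

    use_count = {w: 0 for w in words}
    assign: dict[str, list[int]] = {}
    order = rng.permutation(n)
    for ti in order:
        target = words[ti]
        cands = np.argsort(sim[ti])[::-1]
        picked: list[int] = []
        for ci in cands:
            if len(picked) == n_distractors:
                break
            if use_count[words[ci]] < max_reuse:
                picked.append(int(ci))
                use_count[words[ci]] += 1
        if len(picked) < n_distractors:
            raise ValueError("reuse cap exhausted during greedy assignment")
        assign[target] = picked

    word_index = {w: i for i, w in enumerate(words)}
    totals = {w: float(sim[word_index[w], assign[w]].sum()) for w in words}
    for _ in range(balance_sweeps):
        improved = False
        med = float(np.median(list(totals.values())))
        for target in sorted(words, key=lambda w: -abs(totals[w] - med)):
            ti = word_index[target]
            current = assign[target]
            best = None
            for slot, di in enumerate(current):
                for ci in range(n):
                    if ci == ti or ci in current:
                        continue
                    if use_count[words[ci]] >= max_reuse:
                        continue
                    new_total = totals[target] - sim[ti, di] + sim[ti, ci]
                    if abs(new_total - med) + 1e-12 < abs(totals[target] - med):
                        if best is None or abs(new_total - med) < best[0]:
                            best = (abs(new_total - med), slot, di, ci, new_total)
            if best is not None:
                _, slot, di, ci, new_total = best
                use_count[words[di]] -= 1
                use_count[words[ci]] += 1
                current[slot] = ci
                totals[target] = new_total
                improved = True
        if not improved:
            break

    distractors = {w: tuple(words[i] for i in assign[w]) for w in words}
    return DistractorMap(distractors=distractors, summed_similarity=dict(totals))
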