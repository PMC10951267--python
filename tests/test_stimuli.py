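"""Stimulus engine: SNR sampling functions, word images, filtering, movies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import temposample as ts
from temposample.stimuli import _radial_response, apply_contrast


class TestSamplingFunction:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_normalized_span(self, seed):
        s = ts.generate_snr_function(seed)
        assert len(s) == 24
        assert abs(s.values.min()) < 1e-9
        assert abs(s.values.max() - 0.75) < 1e-9

    def test_deterministic(self):
        a = ts.generate_snr_function(42)
        b = ts.generate_snr_function(42)
        np.testing.assert_array_equal(a.values, b.values)

    @pytest.mark.parametrize("seed", [0, 1, 99, 2**30])
    def test_band_purity(self, seed):
        """Power only at 5..55 Hz: after the affine normalization the DFT may
        gain a DC term but nothing at the 60 Hz Nyquist bin or anywhere else
        off the 5 Hz component grid (24 samples at 120 Hz put every component
        exactly on a bin)."""
        s = ts.generate_snr_function(seed)
        spec = np.fft.rfft(s.values)
        assert abs(spec[-1]) < 1e-9 * np.abs(spec).max()  # Nyquist bin empty

    def test_single_component_is_rescaled_sinusoid(self):
        """With one 20 Hz component the result is an affine map of the
        sinusoid into [0, 0.75]."""
        t = np.arange(24) / 120.0
        wave = np.cos(2 * np.pi * 20.0 * t)
        expected = (wave - wave.min()) / (wave.max() - wave.min()) * 0.75
        # emulate the generator's normalization on a forced single component
        s = ts.generate_snr_function(0, freqs=[20.0])
        # the drawn phase is random, so compare the normalized *spectra*
        assert abs(s.values.min()) < 1e-12 and abs(s.values.max() - 0.75) < 1e-12
        spec = np.abs(np.fft.rfft(s.values - s.values.mean()))
        assert spec.argmax() == 4  # 20 Hz bin
        np.testing.assert_allclose(expected.min(), 0.0, atol=1e-12)

    def test_batch_matches_invariants(self):
        S = ts.generate_snr_batch(5, 100)
        assert S.shape == (100, 24)
        np.testing.assert_allclose(S.min(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(S.max(axis=1), 0.75, atol=1e-9)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            ts.generate_snr_function(0, n_frames=1)


class TestWordRendering:
    def test_word_width_and_range(self):
        img = ts.render_word_image("achat", px_per_deg=32.0)
        ink = img.pixels < 0.5
        cols = np.where(ink.any(axis=0))[0]
        width = cols[-1] - cols[0] + 1
        assert abs(width - 3.4 * 32) <= 0.1 * 3.4 * 32  # ±10% glyph tolerance
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
        side = round(8.9 * 32)
        assert img.shape == (side, side)

    def test_deterministic(self):
        a = ts.render_word_image("punch", 32.0)
        b = ts.render_word_image("punch", 32.0)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="5-letter"):
            ts.render_word_image("abcdef", 32.0)

    def test_unrenderable_character_named(self):
        with pytest.raises(ValueError, match="' '"):
            ts.render_word_image("a b c", 32.0)


class TestButterworth:
    def test_gain_at_center_and_cutoffs(self):
        """Radial FFT gain of the filter: ~1 at 1.2 cpd, half power at the
        0.9 / 1.5 cpd cutoffs (image sized so those fall on the grid)."""
        n = 320  # 32 px/deg -> grid spacing 0.1 cpd
        imp = np.zeros((n, n))
        imp[n // 2, n // 2] = 1.0
        out = ts.butterworth_bandpass(ts.LuminanceImage(imp, 32.0), ts.CONDITION_FILTERS[1])
        gain = np.abs(np.fft.fft2(out.pixels - out.pixels.mean()))
        f = np.hypot(*np.meshgrid(np.fft.fftfreq(n) * 32, np.fft.fftfreq(n) * 32))
        for target, expect in ((1.2, 1.0), (0.9, np.sqrt(0.5)), (1.5, np.sqrt(0.5))):
            idx = np.unravel_index(np.argmin(np.abs(f - target)), f.shape)
            assert f[idx] == pytest.approx(target, abs=1e-9)
            assert gain[idx] == pytest.approx(expect, abs=2e-3)

    def test_dc_only_image_unchanged(self):
        img = ts.LuminanceImage(np.full((64, 64), 0.37), 32.0)
        out = ts.butterworth_bandpass(img, ts.CONDITION_FILTERS[2])
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-12)

    def test_condition_table(self):
        expected = {1.2: (0.9, 1.5), 2.4: (1.8, 3.0), 4.8: (3.6, 6.0), 9.6: (7.2, 12.0)}
        table = {
            s.center_freq: (s.low_cut, s.high_cut) for s in ts.CONDITION_FILTERS.values()
        }
        assert table == expected

    def test_double_application_squares_response(self):
        """Filtering twice equals one pass of the squared-gain filter."""
        rng = np.random.default_rng(0)
        img = ts.LuminanceImage(rng.uniform(0, 1, (128, 128)), 32.0)
        spec = ts.CONDITION_FILTERS[3]
        twice = ts.butterworth_bandpass(ts.butterworth_bandpass(img, spec), spec)
        gain2 = _radial_response((128, 128), 32.0, spec) ** 2
        dev = img.pixels - img.pixels.mean()
        once_sq = np.fft.ifft2(np.fft.fft2(dev) * gain2).real + img.pixels.mean()
        np.testing.assert_allclose(twice.pixels, once_sq, rtol=0, atol=1e-6)

    def test_nyquist_violation_rejected(self):
        img = ts.LuminanceImage(np.zeros((32, 32)), px_per_deg=16.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ts.butterworth_bandpass(img, ts.CONDITION_FILTERS[4])  # 12 cpd >= 8

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ts.FilterSpec(center_freq=1.0, low_cut=1.5, high_cut=2.0)


class TestNoiseAndMovie:
    def test_noise_deterministic_and_independent(self):
        a = ts.generate_noise_field((64, 64), seed=1)
        b = ts.generate_noise_field((64, 64), seed=1)
        c = ts.generate_noise_field((64, 64), seed=2)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        r = np.corrcoef(a.pixels.ravel(), c.pixels.ravel())[0, 1]
        assert abs(r) < 3.0 / np.sqrt(64 * 64)

    def test_noise_mean_luminance(self):
        x = ts.generate_noise_field((128, 128), seed=3).pixels
        se = np.sqrt(1.0 / 12.0 / x.size)  # U[0,1] variance / N
        assert abs(x.mean() - 0.5) < 3 * se

    def test_movie_boundaries(self):
        sig = ts.LuminanceImage(np.full((16, 16), 0.8), 32.0)
        noise = ts.generate_noise_field((16, 16), seed=7)
        vals = np.zeros(24)
        vals[0], vals[1] = 0.0, 0.75
        snr = ts.SamplingFunction(values=vals)
        movie = ts.compose_stimulus_movie(sig, noise, snr, contrast=100.0)
        assert len(movie.frames) == 24
        np.testing.assert_array_equal(movie.frames[0].pixels, noise.pixels)
        expected = np.clip(0.75 * sig.pixels + 0.25 * noise.pixels, 0, 1)
        np.testing.assert_allclose(movie.frames[1].pixels, expected, atol=1e-12)

    def test_movie_shape_mismatch(self):
        sig = ts.LuminanceImage(np.zeros((8, 8)), 32.0)
        noise = ts.LuminanceImage(np.zeros((9, 9)), 32.0)
        snr = ts.generate_snr_function(0)
        with pytest.raises(ValueError, match="shape"):
            ts.compose_stimulus_movie(sig, noise, snr, 50.0)

    def test_rms_contrast_monotone(self):
        img = ts.render_word_image("achat", 16.0)
        filt = ts.butterworth_bandpass(img, ts.CONDITION_FILTERS[2])
        rms = [np.std(apply_contrast(filt, c)) for c in (10.0, 30.0, 60.0, 100.0)]
        assert all(a < b for a, b in zip(rms, rms[1:]))


class TestDistractors:
    def test_four_word_bank_forced(self, rng):
        bank = {
            w: ts.LuminanceImage(rng.uniform(0, 1, (8, 8)), 32.0)
            for w in ("alpha", "bravo", "carol", "delta")
        }
        dm = ts.select_distractors(bank, max_reuse=10)
        for w, ds in dm.distractors.items():
            assert set(ds) == set(bank) - {w}

    def test_no_self_target_and_reuse_cap(self, small_word_bank):
        dm = ts.select_distractors(small_word_bank, max_reuse=6, seed=0)
        counts = {}
        for w, ds in dm.distractors.items():
            assert len(ds) == 3 and w not in ds
            for d in set(ds):
                counts[d] = counts.get(d, 0) + 1
        assert max(counts.values()) <= 6

    def test_infeasible_cap_rejected(self, small_word_bank):
        with pytest.raises(ValueError, match="infeasible"):
            ts.select_distractors(small_word_bank, max_reuse=1)

    def test_spread_beats_random_assignment(self, small_word_bank):
        """The balancing pass keeps summed similarity more even across
        targets than random assignment, on average over seeds."""
        words = sorted(small_word_bank)
        sim = {
            (a, b): ts.image_cross_correlation(small_word_bank[a], small_word_bank[b])
            for a in words for b in words if a != b
        }
        dm = ts.select_distractors(small_word_bank, max_reuse=6, seed=0)
        sums = np.array([dm.summed_similarity[w] for w in words])
        spread_heur = sums.max() - sums.min()
        rng = np.random.default_rng(0)
        spreads = []
        for _ in range(100):
            tot = []
            for w in words:
                others = [x for x in words if x != w]
                pick = rng.choice(others, size=3, replace=False)
                tot.append(sum(sim[(w, d)] for d in pick))
            tot = np.asarray(tot)
            spreads.append(tot.max() - tot.min())
        assert spread_heur <= np.mean(spreads)
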