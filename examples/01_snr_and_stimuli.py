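"""Build one trial's stimulus: word image, bandpass filter, noise, SNR movie.

The SNR sampling function is the independent variable of the whole paradigm:
a random sum of 5-55 Hz sinusoids, normalized to [0, 0.75], that sets the
signal/noise mixing weight of each of the 24 display frames (200 ms at
120 Hz).
"""

import numpy as np

import temposample as ts

snr = ts.generate_snr_function(seed=7)
print("SNR trajectory  min %.3f  max %.3f  mean %.3f" %
      (snr.values.min(), snr.values.max(), snr.values.mean()))
print("first 6 frames:", np.round(snr.values[:6], 3))

word = ts.render_word_image("achat", px_per_deg=32.0)
ink = word.pixels < 0.5
width_px = np.ptp(np.where(ink.any(axis=0))[0]) + 1
print(f"word image {word.shape}, ink width {width_px} px "
      f"(target 3.4 deg x 32 px/deg = {3.4 * 32:.0f} px)")

spec = ts.CONDITION_FILTERS[2]  # 2.4 cpd band (1.8-3.0 cpd half-power)
filtered = ts.butterworth_bandpass(word, spec)
print(f"condition-2 filter: center {spec.center_freq} cpd, "
      f"band {spec.low_cut}-{spec.high_cut} cpd, "
      f"~{spec.cycles_per_letter:.1f} cycles/letter")

noise = ts.generate_noise_field(word.shape, seed=11)
movie = ts.compose_stimulus_movie(filtered, noise, snr, contrast=35.0,
                                  signal_id="achat")
print(f"movie: {len(movie.frames)} frames; luminance SD per frame:")
for t in (int(snr.values.argmin()), int(snr.values.argmax())):
    print(f"  frame {t:2d}: snr={snr.values[t]:.2f}  "
          f"frame SD={movie.frames[t].pixels.std():.4f}")
# At snr=0 the frame is exactly the noise field (SD of U[0,1] ~ 0.289); at
# snr=0.75 the noise weight drops to 0.25 and the frame is dominated by the
# much smoother filtered word, so its luminance SD falls.
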