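"""Detect a weak tone in noise with the statistical sinusoid detector.

Trains the sinusoid/noise peak models on a synthetic corpus (this takes a few
seconds), embeds a random tone at 0 dB band-local SNR in white noise, and
prints the detected tracks and the per-frame detection quality.
"""

import numpy as np

from alarmdet import sinusoid, synth
from alarmdet.spectral import compute_spectrogram

FS = 24000.0

print("training peak models on a synthetic sinusoid corpus ...")
models = sinusoid.train_peak_models(rng_seed=1)

wave, (onset, offset), freq = synth.synth_tone_in_noise(0.0, seed=42)
spec = compute_spectrogram(wave, FS, "rectangular", 2048, 1024, 2048)
print(f"tone at {freq:.0f} Hz, 0 dB local SNR, frames {spec.n_frames}")

tracks = sinusoid.detect_sinusoid_tracks(spec, models)
for t in tracks:
    f_hz = t.bins.mean() * FS / spec.dft_size
    print(f"  track: frames {t.onset}-{t.offset} near {f_hz:.0f} Hz, "
          f"mean energy {t.mean_energy_db:.1f} dB")

covered = sinusoid.sinusoid_frame_decisions(spec, models, freq)
times = spec.frame_times
truth = (times >= onset) & (times + 2048 / FS <= offset)
recall = np.mean(covered[truth])
print(f"frame-level recall on tone frames: {recall:.2f} "
      "(frames fully inside the tone covered by an in-band track)")
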