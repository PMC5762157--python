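"""Extract acoustic feature tracks and the 101-entry summary vector.

Synthesizes one syllable as audio (harmonic stack plus noise), computes the
short-time spectrogram (9.27 ms window, 7.91 ms overlap), the ten per-frame
feature tracks, and the 101-entry summary vector (10 features x 10
statistics + duration) used to embed syllables in feature space.
"""

import songeval as se

repertoire = se.make_tutor_repertoire(1, seed=1)
(wave, rate), _ = se.render_rendition(
    repertoire[0], se.DistortionSpec(delta=0.2, seed=4), mode="waveform")
print(f"waveform: {wave.size} samples at {rate} Hz "
      f"({wave.size / rate * 1000:.0f} ms)")

spec = se.compute_spectrogram(wave, rate)
print(f"spectrogram: {spec.power.shape[0]} frequency bins x "
      f"{spec.power.shape[1]} frames, step {spec.step_s * 1000:.2f} ms")

track = se.compute_feature_tracks(spec, syllable_id="example")
ent = track.data["wiener_entropy"]
f0 = track.data["fundamental_frequency"]
print(f"Wiener entropy mean {ent.mean():.2f} (0 = noise-like, "
      f"negative = tonal); F0 median {f0.median():.0f} Hz")

vec = se.summarize_features(track)
print(f"summary vector: {len(vec)} entries, e.g.")
for name in ["wiener_entropy_mean", "fundamental_frequency_trend_r",
             "pitch_goodness_max", "duration"]:
    print(f"  {name} = {vec[name]:.4f}")
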