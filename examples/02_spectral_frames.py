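"""From a recording to classifier inputs: segmentation and FFT frames.

Cuts a 60 s recording into 24 windows of 10,000 samples (2.5 s each),
transforms each to its normalized magnitude spectrum and reports where the
spectral energy concentrates — inside the 100-500 Hz bowel-sound band.
"""

import numpy as np

from bowelwarn import preprocess, synth

rec = synth.generate_recording(synth.SynthConfig(), label=1, rng_seed=3)
segments = preprocess.segment_recording(rec)
print(f"{len(rec.samples)} samples -> {len(segments)} segments "
      f"of {preprocess.WINDOW}")

frames = [preprocess.fft_transform(s) for s in segments]
values = np.stack([f.values for f in frames])
print(f"frame matrix {values.shape}, range "
      f"[{values.min():.3f}, {values.max():.3f}]")

# Peak bin of the loudest frame, converted back to Hz (two-sided spectrum:
# bin b corresponds to b * 4000 / 10000 Hz for b < 5000).
loudest = int(np.argmax([v.max() for v in values]))
peak_bin = int(np.argmax(values[loudest][:5000]))
print(f"loudest frame {loudest}: peak at bin {peak_bin} "
      f"= {peak_bin * 4000 / 10000:.0f} Hz (burst band is 100-500 Hz)")
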