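"""Filter a recording, detect beats and segment fixed-length cycles.

The chain is: fourth-order Butterworth bandpass 0.5-100 Hz -> 50 Hz
notch (both zero-phase) -> recording-level z-score -> Pan-Tompkins-style
beat detection on the rectified signal -> per-beat windows of
[-0.3, +0.5] median RR resampled to 224 samples and min-max scaled.
"""

import numpy as np

from mcgscreen import synthetic
from mcgscreen.preprocess import (
    bandpass_filter,
    detect_beats,
    notch_filter,
    segment_cycles,
    zscore_normalize,
)

rec = synthetic.generate_cohort(1, 1, 15, fs=1000.0, seed=3)[0]  # the healthy subject
x = bandpass_filter(rec.samples, rec.fs)
x = notch_filter(x, rec.fs)
x = zscore_normalize(x)
peaks = detect_beats(x, rec.fs)
cycles = segment_cycles(x, rec.fs, peaks, subject_id=rec.subject_id, label=rec.label)

rr = np.diff(peaks) / rec.fs
print(f"{rec.subject_id}: {peaks.size} beats detected, median RR {np.median(rr)*1000:.0f} ms")
print(f"{len(cycles)} cycles of length {cycles[0].x.size}, values in "
      f"[{cycles[0].x.min():.0f}, {cycles[0].x.max():.0f}]")
print("each cycle is the direct input to the RP/GASF/MTF image encoders")
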