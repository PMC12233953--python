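"""Photometry preprocessing on a synthetic two-channel recording.

Builds a 10-minute 20 Hz recording with photobleaching, a motion artifact
shared between the 470 nm signal and 415 nm reference channels, and sparse
dLight-like transients; then runs airPLS baseline removal, robust
isosbestic correction, and z-scoring, and checks how well the known
transients are recovered.
"""

import numpy as np

from beliefbandit.photometry import (make_synthetic_recording, preprocess,
                                     align_to_event, da_peak_trough)

rng = np.random.default_rng(5)
events = np.sort(rng.choice(np.arange(5.0, 595.0, 0.05), 80, replace=False))
amps = rng.uniform(0.5, 1.5, 80)
rec = make_synthetic_recording(events, amps, duration=600.0, snr=4.0, rng=rng)

z = preprocess(rec["signal_470"], rec["reference_415"])
r = np.corrcoef(z, rec["transients"])[0, 1]
print(f"correlation of Z(DA) with ground-truth transients: r = {r:.3f}")
print(f"Z(DA) mean = {z.mean():.2e}, SD = {z.std():.6f}")

mat, offs = align_to_event(z, rec["timestamps"], events, (1.0, 2.0),
                           de_base=True)
peaks = np.array([da_peak_trough(row, offs, rewarded=True) for row in mat])
print(f"mean event-locked DA peak over 1 s post-event: {peaks.mean():.2f}")
print("The correlation shows bleach and motion artifact are removed while "
      "transients survive; the peak summary is what trial-level regressions "
      "consume as DA-PT.")
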