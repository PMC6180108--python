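"""Simulate a resting EEG with known vigilance ground truth, then stage it.

An 'adaptive' arousal-regulation profile drifts gradually from relaxed
wakefulness (A stages) towards drowsiness (B stages) over 15 minutes.  We
synthesize the multichannel EEG for that stage sequence and run the automatic
per-second stage classifier; the printed agreement is the fraction of 1-s
segments whose recovered stage matches the ground truth.
"""

import numpy as np

from vigikit import (RegulationProfile, StageSignatureModel, classify_recording,
                     simulate_stage_sequence, synthesize_eeg)

truth = simulate_stage_sequence(RegulationProfile.adaptive(), duration_s=900,
                                seed=7)
recording = synthesize_eeg(truth, signature=StageSignatureModel(snr=10.0),
                           seed=7)
predicted = classify_recording(recording)

agreement = np.mean([a is b for a, b in zip(predicted.stages, truth.stages)])
print(f"recording: {recording.n_channels} channels, "
      f"{recording.duration_s:.0f} s at {recording.fs:.0f} Hz")
print(f"round-trip agreement with ground truth: {agreement:.1%}")
print("stage mix (predicted):")
values, counts = np.unique([s.value for s in predicted.stages],
                           return_counts=True)
for v, c in zip(values, counts):
    print(f"  {v:>8}: {c:4d} s")
# Agreement well above 90% means the spectral/event signatures of each stage
# are recovered reliably at this signal-to-noise ratio.
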