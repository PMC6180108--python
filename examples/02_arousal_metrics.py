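"""Arousal parameters of a vigilance timecourse: composition, MVV, ASS.

The Mean Vigilance Value (MVV) averages per-segment stage scores (stage C = 1
... stage 0 = 6); the Arousal Stability Score (ASS, 1-11) captures how deep
and how early the timecourse declines (11 = rigid high arousal, 1 = sleep
onset within the first five minutes).
"""

from vigikit import RegulationProfile, compute_metrics, simulate_stage_sequence

for name, profile in [("hyperstable", RegulationProfile.hyperstable()),
                      ("adaptive", RegulationProfile.adaptive()),
                      ("instable", RegulationProfile.instable())]:
    tc = simulate_stage_sequence(profile, duration_s=900, seed=3)
    m = compute_metrics(tc)
    pct = ", ".join(f"{k}: {v:.0f}%" for k, v in m.percentages.items() if v >= 1)
    print(f"{name:>12}:  MVV = {m.mvv:.2f}   ASS = {m.ass:2d}   ({pct})")
# Hyperstable regulation keeps MVV near 6 and ASS at 10-11; instable
# regulation collapses to B/C stages immediately, giving ASS 1-4.
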