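"""Score the 6-item Bech depression subscale and classify treatment response.

Response to the sleep-deprivation intervention requires a *strictly* more
than 50% drop of the subscore from baseline — a drop from 8 to exactly 4 is
a non-response.
"""

from vigikit import classify_response, hdrs_bech

baseline_items = {
    "depressed_mood": 2, "guilt": 1, "work_and_activities": 2,
    "retardation": 1, "anxiety_psychic": 1, "somatic_symptoms_general": 1,
}
baseline = hdrs_bech(baseline_items)
print(f"baseline Bech subscore: {baseline}")

for post in (4, 3):
    resp = classify_response(baseline, post)
    drop = 100 * (baseline - post) / baseline
    print(f"  post = {post} ({drop:.1f}% reduction) -> "
          f"{'responder' if resp else 'non-responder'}")
# The boundary matters: 50.0% is not 'more than 50%'.
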