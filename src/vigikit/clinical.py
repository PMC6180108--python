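"""Clinical instrument scoring and treatment-response classification.

The change-sensitive 6-item melancholia subscore of the Hamilton Depression
Rating Scale (depressed mood, guilt, work and activities, retardation,
psychic anxiety, general somatic symptoms) is the outcome used to classify
response to partial sleep deprivation: a responder's subscore drops by
*strictly more than* 50% from baseline.  The strict inequality matters at the
boundary — a drop from 8 to 4 (exactly 50%) is a non-response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["HDRS_BECH_ITEMS", "SubjectRecord", "hdrs_bech", "classify_response",
           "split_cohort"]

#: the six Bech items with their HDRS scoring ranges
HDRS_BECH_ITEMS: dict[str, tuple[int, int]] = {
    "depressed_mood": (0, 4),
    "guilt": (0, 4),
    "work_and_activities": (0, 4),
    "retardation": (0, 4),
    "anxiety_psychic": (0, 4),
    "somatic_symptoms_general": (0, 2),
}


def hdrs_bech(items) -> int:
    """Sum the six Bech HDRS items.

    ``items`` is a mapping (item name -> score) or a sequence of six scores in
    the canonical item order.  Missing or out-of-range values raise — scores
    with missing information are excluded, never imputed.
    """
    names = list(HDRS_BECH_ITEMS)
    if isinstance(items, Mapping):
        missing = [k for k in names if k not in items]
        if missing:
            raise ValueError(f"missing HDRS items: {missing}")
        extra = [k for k in items if k not in names]
        if extra:
            raise ValueError(f"unexpected HDRS items: {extra}")
        values = {k: items[k] for k in names}
    else:
        seq = list(items)
        if len(seq) != 6:
            raise ValueError(f"expected exactly 6 item scores, got {len(seq)}")
        values = dict(zip(names, seq))
    total = 0
    for name, v in values.items():
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"HDRS item {name!r} is missing")
        v = int(v)
        lo, hi = HDRS_BECH_ITEMS[name]
        if not lo <= v <= hi:
            raise ValueError(f"HDRS item {name!r} = {v} outside range [{lo}, {hi}]")
        total += v
    return total


def classify_response(baseline: float, post: float) -> bool:
    """True iff the score dropped by strictly more than 50% from baseline.

    ``baseline`` must be positive; a zero baseline leaves the response
    undefined and raises.
    """
    if baseline <= 0:
        raise ValueError("response undefined for a non-positive baseline score")
    return (baseline - post) / baseline > 0.5


@dataclass
class SubjectRecord:
    """Per-subject clinical record across the two assessment days."""

    id: str
    group: str                                   # "patient" | "control"
    age: float
    sex: str                                     # "m" | "f"
    hdrs_items: dict = field(default_factory=dict)   # day -> item dict
    hdrs17: dict = field(default_factory=dict)       # day -> total
    ids_c: Optional[float] = None
    sss: dict = field(default_factory=dict)          # day -> 1..7
    asts: dict = field(default_factory=dict)         # (day, subscale) -> score
    status: Optional[str] = None                     # generative cell label

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be 'patient' or 'control', got {self.group!r}")
        for day, v in self.sss.items():
            if not 1 <= int(v) <= 7:
                raise ValueError(f"SSS score {v} on {day} outside 1..7")

    def hdrs_bech_score(self, day: str) -> int:
        return hdrs_bech(self.hdrs_items[day])

    @property
    def responder(self) -> Optional[bool]:
        """Response flag (patients with both scores only)."""
        if self.group != "patient":
            return None
        if "baseline" not in self.hdrs_items or "post" not in self.hdrs_items:
            return None
        return classify_response(self.hdrs_bech_score("baseline"),
                                 self.hdrs_bech_score("post"))


def _describe(records: Sequence[SubjectRecord]) -> dict:
    def ms(vals):
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        if not vals:
            return (np.nan, np.nan)
        return (float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan)

    out = {"n": len(records)}
    out["n_male"] = sum(1 for r in records if r.sex == "m")
    out["n_female"] = sum(1 for r in records if r.sex == "f")
    out["age_mean"], out["age_sd"] = ms([r.age for r in records])
    out["hdrs_bech_baseline_mean"], out["hdrs_bech_baseline_sd"] = ms(
        [r.hdrs_bech_score("baseline") for r in records if "baseline" in r.hdrs_items])
    post = [r.hdrs_bech_score("post") for r in records if "post" in r.hdrs_items]
    out["hdrs_bech_post_mean"], out["hdrs_bech_post_sd"] = ms(post)
    out["hdrs17_mean"], out["hdrs17_sd"] = ms(
        [r.hdrs17.get("baseline") for r in records])
    out["ids_c_mean"], out["ids_c_sd"] = ms([r.ids_c for r in records])
    out["sss_baseline_mean"], out["sss_baseline_sd"] = ms(
        [r.sss.get("baseline") for r in records])
    out["sss_post_mean"], out["sss_post_sd"] = ms([r.sss.get("post") for r in records])
    return out


def split_cohort(records: Sequence[SubjectRecord]) -> dict:
    """Split patients into responders / non-responders with descriptives.

    Returns a dict with explicit counts (zero for empty groups) and one
    descriptive-statistics table per group (responders, non-responders, and —
    when present — controls).
    """
    patients = [r for r in records if r.group == "patient"]
    controls = [r for r in records if r.group == "control"]
    missing = [r.id for r in patients if r.responder is None]
    if missing:
        raise ValueError(f"patients lacking both HDRS scores: {missing}")
    resp = [r for r in patients if r.responder]
    nonresp = [r for r in patients if not r.responder]
    tables = {name: pd.DataFrame([_describe(g)]) for name, g in
              [("responders", resp), ("non_responders", nonresp)]}
    if controls:
        tables["controls"] = pd.DataFrame([_describe(controls)])
    return {
        "n_responders": len(resp),
        "n_non_responders": len(nonresp),
        "responders": resp,
        "non_responders": nonresp,
        "tables": tables,
    }
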