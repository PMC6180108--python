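"""Arousal parameters computed from a vigilance timecourse.

Three parameters summarise a 15-min eyes-closed resting recording:

1. **Stage composition** — absolute counts and percentages of each stage
   (percent = count * 100 / number of non-artifact segments), overall and per
   recording minute.
2. **Mean Vigilance Value (MVV)** — mean of the per-segment ordinal scores
   (C = 1 ... 0 = 6) over non-artifact segments, overall and per minute.
3. **Arousal Stability Score (ASS)** — ordinal 1-11 score quantifying how deep
   and how early the vigilance time course declines.  Successive 1-min blocks
   are checked against a criteria ladder (deepest criterion wins, and within a
   criterion the earliest fulfilling block's 5-min window selects the score):

   =====  ==============================================  ==================
   level  blockwise criterion                             scores (win 1/2/3)
   =====  ==============================================  ==================
   4      at least one stage-C segment                    1 / 2 / 3
   3      >= 1/3 of segments are B2/3                     4 / 5 / 6
   2      >= 1/3 of segments are B (B1 + B2/3)            7 / 8 / 9
   1      (whole recording) neither of the above          10 or 11
   =====  ==============================================  ==================

   where window 1 = minutes 1-5, window 2 = minutes 6-10, window 3 = minutes
   11-15.  At level 1 a score of 11 marks rigidity (essentially only 0/A1
   segments), 10 a recording that still stays within the high 0/A range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .stages import STAGE_ORDER, STAGE_SCORES, Stage, VigilanceTimecourse

__all__ = [
    "ArousalMetrics",
    "stage_composition",
    "mean_vigilance_value",
    "arousal_stability_score",
    "compute_metrics",
]

_B_STAGES = (Stage.B1, Stage.B23)
_HIGH_0A1 = (Stage.ZERO, Stage.A1)
_HIGH_0A = (Stage.ZERO, Stage.A1, Stage.A23)


@dataclass
class ArousalMetrics:
    """Bundle of the arousal parameters for one recording."""

    counts: dict
    percentages: dict
    per_minute: pd.DataFrame
    mvv: float
    mvv_per_minute: list
    ass: int
    n_artifact: int
    subject: Optional[str] = None
    day: Optional[str] = None

    def to_row(self) -> dict:
        row = {"subject": self.subject, "day": self.day, "mvv": self.mvv,
               "ass": self.ass, "n_artifact": self.n_artifact}
        for s in STAGE_ORDER:
            row[f"pct_{s.value}"] = self.percentages[s.value]
        return row


def _nonartifact(tc: VigilanceTimecourse) -> np.ndarray:
    keep = ~tc.artifact_mask
    if not keep.any():
        raise ValueError("timecourse contains no non-artifact segments")
    return tc.stages[keep]


def stage_composition(tc: VigilanceTimecourse, per_minute: bool = False):
    """Stage counts and percentages over non-artifact segments.

    With ``per_minute=True`` returns a tidy DataFrame with one row per
    (minute, stage); otherwise a ``(counts, percentages)`` pair of dicts keyed
    by stage value.  Artifacts are excluded from every denominator.
    """
    if per_minute:
        rows = []
        for m, block in enumerate(tc.blocks(60.0), start=1):
            keep = np.array([s is not Stage.ARTIFACT for s in block], dtype=bool)
            nb = int(keep.sum())
            for s in STAGE_ORDER:
                cnt = int(sum(1 for x in block[keep] if x is s))
                rows.append({"minute": m, "stage": s.value, "count": cnt,
                             "percent": (100.0 * cnt / nb) if nb else np.nan})
        return pd.DataFrame(rows)
    stages = _nonartifact(tc)
    n = stages.size
    counts = {s.value: int(sum(1 for x in stages if x is s)) for s in STAGE_ORDER}
    pct = {k: 100.0 * v / n for k, v in counts.items()}
    return counts, pct


def mean_vigilance_value(tc: VigilanceTimecourse, per_minute: bool = False):
    """Mean of per-segment vigilance scores over non-artifact segments.

    The overall MVV lies in [1, 6]; the per-minute variant returns one value
    per 60-s block (NaN for all-artifact blocks).
    """
    scores = tc.scores()
    if per_minute:
        per = int(round(60.0 / tc.epoch_s))
        out = []
        for i in range(0, tc.n_epochs, per):
            blk = scores[i:i + per]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out.append(float(np.nanmean(blk)) if np.isfinite(blk).any() else np.nan)
        return out
    if not np.isfinite(scores).any():
        raise ValueError("timecourse contains no non-artifact segments")
    return float(np.nanmean(scores))


def _window_of_block(block_idx: int, n_blocks: int, lenient: bool) -> int:
    """Map a 0-based block index to the 5-min window index 0/1/2."""
    if not lenient or n_blocks == 15:
        return min(2, block_idx // 5)
    # lenient mode for non-15-min recordings: equal thirds
    return min(2, block_idx * 3 // n_blocks)


def arousal_stability_score(
    tc: VigilanceTimecourse,
    strict_duration: bool = True,
    level1_rule: str = "fraction",
    block_s: float = 60.0,
    artifact_block_max: float = 0.5,
) -> int:
    """Arousal Stability Score (1-11) for a vigilance timecourse.

    Parameters
    ----------
    strict_duration
        When True (default) the timecourse must span exactly 15 one-minute
        blocks; when False, blocks are mapped onto thirds of the recording for
        the window lookup.
    level1_rule
        ``"fraction"`` (default): score 11 when less than 1/3 of all
        non-artifact segments fall outside {0, A1}, else 10.
        ``"literal"``: score 11 only when *exclusively* 0/A1 segments occur,
        10 when exclusively 0/A segments occur; otherwise falls back to the
        fractional rule.
    artifact_block_max
        Blocks with a higher artifact fraction are skipped (with a warning)
        when evaluating the blockwise criteria.
    """
    if level1_rule not in ("fraction", "literal"):
        raise ValueError("level1_rule must be 'fraction' or 'literal'")
    blocks = tc.blocks(block_s)
    n_blocks = len(blocks)
    expected = int(round(900.0 / tc.epoch_s) // int(round(block_s / tc.epoch_s)))
    if strict_duration and n_blocks != 15:
        raise ValueError(
            f"expected a 15-min timecourse (15 blocks of {block_s:g} s), got "
            f"{n_blocks} blocks; pass strict_duration=False to relax"
        )
    del expected

    first_b = first_b23 = first_c = None  # earliest fulfilling block index
    for i, block in enumerate(blocks):
        keep = np.array([s is not Stage.ARTIFACT for s in block], dtype=bool)
        nb = int(keep.sum())
        if nb == 0 or (block.size - nb) / block.size > artifact_block_max:
            warnings.warn(f"block {i + 1}: >{artifact_block_max:.0%} artifacts, skipped")
            continue
        seg = block[keep]
        n_c = sum(1 for s in seg if s is Stage.C)
        n_b23 = sum(1 for s in seg if s is Stage.B23)
        n_b = n_b23 + sum(1 for s in seg if s is Stage.B1)
        if n_c >= 1 and first_c is None:
            first_c = i
        if n_b23 / nb >= 1.0 / 3.0 and first_b23 is None:
            first_b23 = i
        if n_b / nb >= 1.0 / 3.0 and first_b is None:
            first_b = i

    lenient = not strict_duration
    if first_c is not None:
        return 1 + _window_of_block(first_c, n_blocks, lenient)
    if first_b23 is not None:
        return 4 + _window_of_block(first_b23, n_blocks, lenient)
    if first_b is not None:
        return 7 + _window_of_block(first_b, n_blocks, lenient)

    # level 1: stability over the whole recording
    stages = _nonartifact(tc)
    if level1_rule == "literal":
        present = set(stages.tolist())
        if present <= set(_HIGH_0A1):
            return 11
        if present <= set(_HIGH_0A):
            return 10
        # fall through to fractional reading
    frac_outside = sum(1 for s in stages if s not in _HIGH_0A1) / stages.size
    return 11 if frac_outside < 1.0 / 3.0 else 10


def compute_metrics(tc: VigilanceTimecourse, **ass_kwargs) -> ArousalMetrics:
    """Compute the full arousal-parameter bundle for one timecourse."""
    counts, pct = stage_composition(tc)
    return ArousalMetrics(
        counts=counts,
        percentages=pct,
        per_minute=stage_composition(tc, per_minute=True),
        mvv=mean_vigilance_value(tc),
        mvv_per_minute=mean_vigilance_value(tc, per_minute=True),
        ass=arousal_stability_score(tc, **ass_kwargs),
        n_artifact=int(tc.artifact_mask.sum()),
        subject=tc.subject,
        day=tc.day,
    )
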