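"""EEG-vigilance stage taxonomy and per-second stage timecourses.

Six vigilance stages span the continuum from activated wakefulness to sleep
onset.  Each stage carries an ordinal score used by the Mean Vigilance Value:

======  =====  =============================================
stage   score  electrophysiological picture
======  =====  =============================================
0       6      low-amplitude non-alpha EEG, no slow eye movements
A1      5      dominant *occipital* alpha
A2/3    4      alpha shifted anteriorly, reduced amplitude
B1      3      low-amplitude non-alpha EEG with slow eye movements
B2/3    2      theta/delta dominated EEG
C       1      sleep onset: spindles and K-complexes
======  =====  =============================================

Artifact-contaminated segments are labelled ``ARTIFACT`` and never enter any
metric denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["Stage", "STAGE_ORDER", "STAGE_SCORES", "VigilanceTimecourse"]


class Stage(str, Enum):
    """One EEG-vigilance stage label (or ARTIFACT)."""

    ZERO = "0"
    A1 = "A1"
    A23 = "A2/3"
    B1 = "B1"
    B23 = "B2/3"
    C = "C"
    ARTIFACT = "artifact"

    @property
    def score(self) -> Optional[int]:
        """Ordinal vigilance score (6 = stage 0 ... 1 = stage C); None for artifacts."""
        return STAGE_SCORES.get(self)

    @property
    def is_artifact(self) -> bool:
        return self is Stage.ARTIFACT

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: stages ordered from highest vigilance (0) to deepest (C)
STAGE_ORDER: tuple[Stage, ...] = (
    Stage.ZERO,
    Stage.A1,
    Stage.A23,
    Stage.B1,
    Stage.B23,
    Stage.C,
)

STAGE_SCORES: dict[Stage, int] = {
    Stage.ZERO: 6,
    Stage.A1: 5,
    Stage.A23: 4,
    Stage.B1: 3,
    Stage.B23: 2,
    Stage.C: 1,
}

_BY_VALUE = {s.value: s for s in Stage}
_ALIASES = {"ART": Stage.ARTIFACT, "ARTIFACT": Stage.ARTIFACT, "A2": Stage.A23,
            "A3": Stage.A23, "B2": Stage.B23, "B3": Stage.B23}


def as_stage(label) -> Stage:
    """Coerce a label (Stage or string) into a :class:`Stage`."""
    if isinstance(label, Stage):
        return label
    key = str(label).strip()
    if key in _BY_VALUE:
        return _BY_VALUE[key]
    up = key.upper()
    if up in _ALIASES:
        return _ALIASES[up]
    if up in _BY_VALUE:
        return _BY_VALUE[up]
    raise ValueError(f"unknown vigilance stage label: {label!r}")


@dataclass
class VigilanceTimecourse:
    """Per-second vigilance stage sequence for one recording.

    Parameters
    ----------
    stages
        Sequence of :class:`Stage` (or stage strings), one per epoch.
    epoch_s
        Epoch duration in seconds (1 s in the standard analysis).
    subject, day
        Optional identifiers carried through to exported tables.
    """

    stages: np.ndarray
    epoch_s: float = 1.0
    subject: Optional[str] = None
    day: Optional[str] = None

    def __post_init__(self) -> None:
        arr = np.array([as_stage(s) for s in np.asarray(self.stages, dtype=object)],
                       dtype=object)
        if arr.size == 0:
            raise ValueError("timecourse must contain at least one epoch")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        self.stages = arr

    # -- basic views ---------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    @property
    def artifact_mask(self) -> np.ndarray:
        return np.array([s is Stage.ARTIFACT for s in self.stages], dtype=bool)

    def scores(self) -> np.ndarray:
        """Per-epoch vigilance scores as floats, NaN for artifact epochs."""
        return np.array(
            [np.nan if s is Stage.ARTIFACT else STAGE_SCORES[s] for s in self.stages],
            dtype=float,
        )

    def __len__(self) -> int:
        return self.n_epochs

    def __iter__(self) -> Iterator[Stage]:
        return iter(self.stages)

    def __getitem__(self, idx):
        return self.stages[idx]

    # -- blockwise iteration (used by the stability score) -------------
    def blocks(self, block_s: float = 60.0) -> list[np.ndarray]:
        """Split into successive blocks of ``block_s`` seconds (trailing partial kept)."""
        per = int(round(block_s / self.epoch_s))
        if per <= 0:
            raise ValueError("block shorter than one epoch")
        return [self.stages[i:i + per] for i in range(0, self.n_epochs, per)]

    # -- interchange format --------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        sc = self.scores()
        return pd.DataFrame(
            {
                "epoch": np.arange(self.n_epochs),
                "stage": [s.value for s in self.stages],
                "mvv_score": sc,
                "artifact": self.artifact_mask.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "VigilanceTimecourse":
        return cls(stages=np.array([as_stage(s) for s in df["stage"]], dtype=object), **kw)

    @classmethod
    def from_csv(cls, path, **kw) -> "VigilanceTimecourse":
        return cls.from_frame(pd.read_csv(path), **kw)

    @classmethod
    def from_labels(cls, labels: Iterable, **kw) -> "VigilanceTimecourse":
        return cls(stages=np.array(list(labels), dtype=object), **kw)

    def concat(self, other: "VigilanceTimecourse") -> "VigilanceTimecourse":
        if other.epoch_s != self.epoch_s:
            raise ValueError("cannot concatenate timecourses with different epoch lengths")
        return VigilanceTimecourse(
            stages=np.concatenate([self.stages, other.stages]),
            epoch_s=self.epoch_s, subject=self.subject, day=self.day,
        )
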