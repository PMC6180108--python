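"""Vigilance stage classification from per-epoch features.

Every non-artifact 1-s segment is assigned one of six stages by a decision
cascade in which sleep-onset graphoelements dominate (mirroring sleep-scoring
convention):

1. sleep spindle or K-complex            -> C
2. theta/delta dominance, no alpha       -> B2/3
3. alpha-dominant                        -> A1 (occipital alpha) or A2/3
                                            (anteriorized alpha)
4. low-amplitude non-alpha               -> B1 if slow eye movements, else 0

Alpha dominance is decided in two passes against the recording's own feature
distribution: an epoch is alpha-dominant when its best-region alpha share of
1-30 Hz power reaches the share cut *and* its alpha power reaches a fixed
fraction of the median alpha power of provisionally alpha-dominant epochs
(defaults in :class:`StagingConfig`).  All thresholds are ratios or
recording-relative medians, so stage labels are invariant to a global gain
change (as long as nothing crosses the artifact amplitude bound).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import EpochFeatures, extract_features
from .recording import EEGRecording
from .stages import Stage, VigilanceTimecourse

__all__ = ["StagingConfig", "StagingThresholds", "adaptive_thresholds",
           "classify_epoch", "classify_recording"]

logger = logging.getLogger(__name__)


@dataclass
class StagingConfig:
    """Tunable staging parameters (declared defaults, not normative values)."""

    alpha_share_cut: float = 0.45    # best-region alpha share for alpha dominance
    alpha_floor_frac: float = 0.25   # fraction of median alpha power (2nd pass)
    td_share_cut: float = 0.65       # (delta+theta)/total share for B2/3
    anterior_split: float = 1.0      # anteriorization index separating A1 from A2/3
    low_amp_frac: float = 0.7        # EOG-less 0-vs-B1 fallback: rms fraction of median
    artifact_uV: float = 100.0
    spindle_k: float = 3.0


@dataclass
class StagingThresholds:
    """Per-recording adaptive thresholds derived from robust statistics."""

    alpha_power_floor: float         # uV^2; 0 when no alpha-dominant epochs exist
    rms_median: float                # uV, over non-artifact epochs
    config: StagingConfig = field(default_factory=StagingConfig)


def adaptive_thresholds(
    feats: list[EpochFeatures], config: StagingConfig | None = None
) -> StagingThresholds:
    """Derive the recording-adaptive thresholds from all epoch features.

    Requires >= 60 epochs (one recording minute) so the medians are stable.
    The alpha-power floor is ``alpha_floor_frac`` times the median best-region
    alpha power over provisionally alpha-dominant epochs (share >= cut); when
    no epoch is provisionally alpha-dominant the floor is zero and the share
    criterion alone decides.
    """
    config = config or StagingConfig()
    if len(feats) < 60:
        raise ValueError(f"need >= 60 epochs to adapt thresholds, got {len(feats)}")
    clean = [f for f in feats if not f.artifact]
    if not clean:
        raise ValueError("no non-artifact epochs to derive thresholds from")
    totals = np.array([np.mean(list(f.total.values())) for f in clean])
    if np.all(totals <= 0):
        raise ValueError("degenerate feature distribution: all-zero band powers")
    provisional = [f.best_alpha_power for f in clean
                   if f.best_alpha_share >= config.alpha_share_cut]
    floor = config.alpha_floor_frac * float(np.median(provisional)) if provisional else 0.0
    rms_median = float(np.median([f.rms for f in clean]))
    logger.info("adaptive thresholds: alpha_power_floor=%.3g uV^2, rms_median=%.3g uV",
                floor, rms_median)
    return StagingThresholds(alpha_power_floor=floor, rms_median=rms_median,
                             config=config)


_warned_no_eog = False


def classify_epoch(f: EpochFeatures, thresholds: StagingThresholds) -> Stage:
    """Assign a vigilance stage to one epoch (ARTIFACT for artifact epochs)."""
    global _warned_no_eog
    if f.artifact:
        return Stage.ARTIFACT
    cfg = thresholds.config
    if f.spindle or f.kcomplex:
        return Stage.C
    alpha_dom = (f.best_alpha_share >= cfg.alpha_share_cut
                 and f.best_alpha_power >= thresholds.alpha_power_floor)
    if not alpha_dom and f.theta_delta_share() >= cfg.td_share_cut:
        return Stage.B23
    if alpha_dom:
        return Stage.A1 if f.anteriorization < cfg.anterior_split else Stage.A23
    if f.sem is None:
        if not _warned_no_eog:
            warnings.warn("no EOG available: falling back to an amplitude criterion "
                          "for the 0-vs-B1 decision")
            _warned_no_eog = True
        return Stage.B1 if f.rms < cfg.low_amp_frac * thresholds.rms_median else Stage.ZERO
    return Stage.B1 if f.sem else Stage.ZERO


def classify_recording(
    rec: EEGRecording, config: StagingConfig | None = None
) -> VigilanceTimecourse:
    """Stage every 1-s segment of a recording.

    Thresholds are adapted once from the whole recording before labelling, so
    the result is deterministic for a fixed input.
    """
    config = config or StagingConfig()
    feats = extract_features(rec, artifact_uV=config.artifact_uV,
                             spindle_k=config.spindle_k)
    clean = [f for f in feats if not f.artifact]
    if clean:
        thresholds = adaptive_thresholds(feats, config) if len(feats) >= 60 else \
            StagingThresholds(alpha_power_floor=0.0,
                              rms_median=float(np.median([f.rms for f in clean])),
                              config=config)
        labels = [classify_epoch(f, thresholds) for f in feats]
    else:
        labels = [Stage.ARTIFACT] * len(feats)
    return VigilanceTimecourse(
        stages=np.array(labels, dtype=object),
        subject=rec.meta.get("subject"),
        day=rec.meta.get("day"),
    )
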