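"""Seeded cohort generation: subjects, clinical scores and stage sequences.

The default specification emulates a two-day partial-sleep-deprivation (PSD)
study: 17 responder patients, 10 non-responder patients and 16 healthy
controls, each with a 15-min resting EEG stage sequence at baseline and after
the PSD night.  Patients follow a hyperstable arousal-regulation profile at
baseline (responders destabilise to an adaptive profile after PSD); controls
decline from adaptive to instable.  Clinical scores (Bech HDRS subscore, SSS
sleepiness, HDRS-17, IDS-C, age, sex ratio) are drawn around the descriptive
statistics of the emulated design.

Seeds propagate hierarchically (cohort seed -> subject -> recording), so any
single recording is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .clinical import HDRS_BECH_ITEMS, SubjectRecord
from .recording import EEGRecording
from .stages import VigilanceTimecourse
from .synth import (DEFAULT_MONTAGE, RegulationProfile, StageSignatureModel,
                    simulate_stage_sequence, synthesize_eeg)

__all__ = ["CohortCell", "CohortSpec", "Cohort", "generate_cohort"]

DAYS = ("baseline", "post")


@dataclass
class CohortCell:
    """One design cell (group x status) with its generative parameters."""

    name: str
    group: str                      # "patient" | "control"
    n: int
    profiles: dict                  # day -> RegulationProfile
    age_mean: float = 40.0
    age_sd: float = 13.0
    n_female: Optional[int] = None  # exact count; None -> n // 2
    hdrs_mean: float = 8.0          # baseline HDRS_Bech
    hdrs_sd: float = 2.0
    reduction_mean: Optional[float] = None   # post-PSD fractional reduction
    reduction_sd: float = 0.0
    sss_mean: dict = field(default_factory=lambda: {"baseline": 3.7, "post": 3.6})
    sss_sd: dict = field(default_factory=lambda: {"baseline": 1.2, "post": 1.6})
    hdrs17_extra_mean: float = 7.7  # HDRS-17 = Bech + extra (patients)
    hdrs17_extra_sd: float = 1.5
    ids_mean: float = 31.5
    ids_sd: float = 8.2

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"cell {self.name!r} must contain at least one subject")
        if self.reduction_mean is not None and not 0.0 <= self.reduction_mean <= 1.0:
            raise ValueError(f"cell {self.name!r}: reduction fraction outside [0, 1]")
        for day in DAYS:
            if day not in self.profiles:
                raise ValueError(f"cell {self.name!r} lacks a profile for day {day!r}")


@dataclass
class CohortSpec:
    """Full cohort specification (the study conditions)."""

    cells: list
    seed: int = 0
    duration_s: int = 900
    fs: float = 250.0
    montage: tuple = DEFAULT_MONTAGE
    signature: StageSignatureModel = field(default_factory=StageSignatureModel)

    def validate(self) -> None:
        if not self.cells:
            raise ValueError("cohort spec contains no cells")
        for c in self.cells:
            c.validate()

    @classmethod
    def default(cls, seed: int = 0, **kw) -> "CohortSpec":
        """The emulated two-day PSD design (27 patients + 16 controls)."""
        cells = [
            CohortCell(
                name="responder", group="patient", n=17,
                profiles={"baseline": RegulationProfile.hyperstable(),
                          "post": RegulationProfile.adaptive()},
                age_mean=35.71, age_sd=10.457, n_female=12,
                hdrs_mean=8.41, hdrs_sd=2.033,
                reduction_mean=0.755, reduction_sd=0.05,
                sss_mean={"baseline": 3.88, "post": 3.18},
                sss_sd={"baseline": 1.204, "post": 1.667},
                ids_mean=32.94, ids_sd=7.058,
            ),
            CohortCell(
                name="non_responder", group="patient", n=10,
                profiles={"baseline": RegulationProfile.hyperstable(),
                          "post": RegulationProfile.hyperstable()},
                age_mean=48.20, age_sd=16.158, n_female=5,
                hdrs_mean=7.20, hdrs_sd=2.486,
                reduction_mean=0.18, reduction_sd=0.08,
                sss_mean={"baseline": 3.50, "post": 4.20},
                sss_sd={"baseline": 1.354, "post": 1.476},
                ids_mean=29.00, ids_sd=9.730,
            ),
            CohortCell(
                name="control", group="control", n=16,
                profiles={"baseline": RegulationProfile.adaptive(),
                          "post": RegulationProfile.instable()},
                age_mean=37.94, age_sd=13.309, n_female=9,
                hdrs_mean=0.5, hdrs_sd=0.816,
                reduction_mean=None,
                sss_mean={"baseline": 1.69, "post": 2.69},
                sss_sd={"baseline": 0.479, "post": 1.250},
                hdrs17_extra_mean=0.75, hdrs17_extra_sd=0.8,
                ids_mean=1.85, ids_sd=2.734,
            ),
        ]
        return cls(cells=cells, seed=seed, **kw)


def _distribute_items(total: int, rng) -> dict:
    """Distribute a Bech subscore total across the six items within ranges."""
    names = list(HDRS_BECH_ITEMS)
    caps = {k: HDRS_BECH_ITEMS[k][1] for k in names}
    total = int(min(max(total, 0), sum(caps.values())))
    items = {k: 0 for k in names}
    for _ in range(total):
        open_items = [k for k in names if items[k] < caps[k]]
        items[rng.choice(open_items)] += 1
    return items


class Cohort:
    """Generated cohort: subject records plus ground-truth stage sequences.

    EEG recordings are synthesized lazily (:meth:`recording`) so that
    sequence-level analyses stay cheap.
    """

    def __init__(self, spec: CohortSpec, subjects, sequences, seeds):
        self.spec = spec
        self.subjects: list[SubjectRecord] = subjects
        self.sequences: dict[tuple[str, str], VigilanceTimecourse] = sequences
        self._rec_seeds: dict[tuple[str, str], int] = seeds

    def recording(self, subject_id: str, day: str) -> EEGRecording:
        """Synthesize the EEG for one (subject, day); deterministic per cohort seed."""
        tc = self.sequences[(subject_id, day)]
        rec = synthesize_eeg(tc, signature=self.spec.signature,
                             montage=self.spec.montage, fs=self.spec.fs,
                             seed=self._rec_seeds[(subject_id, day)])
        rec.meta.update({"subject": subject_id, "day": day})
        return rec

    def clinical_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append({
                "subject": s.id, "group": s.group, "status": s.status,
                "age": s.age, "sex": s.sex,
                "hdrs_bech_baseline": s.hdrs_bech_score("baseline")
                    if "baseline" in s.hdrs_items else np.nan,
                "hdrs_bech_post": s.hdrs_bech_score("post")
                    if "post" in s.hdrs_items else np.nan,
                "hdrs17_baseline": s.hdrs17.get("baseline", np.nan),
                "ids_c": s.ids_c,
                "sss_baseline": s.sss.get("baseline", np.nan),
                "sss_post": s.sss.get("post", np.nan),
                "responder": s.responder,
            })
        return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort from a validated spec (fully seeded)."""
    spec.validate()
    subjects: list[SubjectRecord] = []
    sequences: dict[tuple[str, str], VigilanceTimecourse] = {}
    rec_seeds: dict[tuple[str, str], int] = {}
    sidx = 0
    for cell in spec.cells:
        n_f = cell.n // 2 if cell.n_female is None else int(cell.n_female)
        sexes = ["f"] * n_f + ["m"] * (cell.n - n_f)
        for k in range(cell.n):
            sid = f"{cell.name}_{k + 1:02d}"
            crng = np.random.default_rng(
                np.random.SeedSequence([int(spec.seed), 1, sidx]))
            age = float(np.clip(crng.normal(cell.age_mean, cell.age_sd), 18, 80))
            baseline_total = int(round(crng.normal(cell.hdrs_mean, cell.hdrs_sd)))
            # cells that undergo response classification need a positive baseline
            floor = 1 if cell.reduction_mean is not None else 0
            baseline_total = max(baseline_total, floor)
            hdrs_items = {"baseline": _distribute_items(baseline_total, crng)}
            if cell.reduction_mean is not None:
                red = crng.normal(cell.reduction_mean, cell.reduction_sd) \
                    if cell.reduction_sd > 0 else cell.reduction_mean
                post_total = int(round(baseline_total * (1.0 - red)))
                hdrs_items["post"] = _distribute_items(
                    int(np.clip(post_total, 0, baseline_total)), crng)
            sss = {}
            for day in DAYS:
                v = crng.normal(cell.sss_mean[day], cell.sss_sd[day]) \
                    if cell.sss_sd[day] > 0 else cell.sss_mean[day]
                sss[day] = int(np.clip(round(v), 1, 7))
            extra = max(0, int(round(crng.normal(cell.hdrs17_extra_mean,
                                                 cell.hdrs17_extra_sd))))
            rec = SubjectRecord(
                id=sid, group=cell.group, age=age, sex=sexes[k],
                hdrs_items=hdrs_items,
                hdrs17={"baseline": baseline_total + extra},
                ids_c=float(max(0.0, crng.normal(cell.ids_mean, cell.ids_sd))),
                sss=sss, status=cell.name,
            )
            subjects.append(rec)
            for d, day in enumerate(DAYS):
                ss = np.random.SeedSequence([int(spec.seed), 2, sidx, d])
                seq_seed, eeg_seed = [int(x) for x in ss.generate_state(2)]
                tc = simulate_stage_sequence(cell.profiles[day], spec.duration_s,
                                             seq_seed)
                tc.subject, tc.day = sid, day
                sequences[(sid, day)] = tc
                rec_seeds[(sid, day)] = eeg_seed
            sidx += 1
    return Cohort(spec, subjects, sequences, rec_seeds)
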