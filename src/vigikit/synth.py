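"""Synthetic resting-EEG generator with known vigilance ground truth.

Arousal regulation is modelled as a latent per-second arousal level

    L(t) = start_level + drift_per_min * t/60 + N(0, volatility)

thresholded by five strictly decreasing cutpoints into the six vigilance
stages.  Three presets reproduce the prototypical regulation patterns:
*hyperstable* (remains in 0/A1 for the whole 15 min), *adaptive* (gradual
decline towards B stages) and *instable* (drops into B/C territory within the
first minute).

Each stage then maps to a spectral recipe (band amplitudes per scalp region)
from which a multichannel signal is synthesized: band-limited Gaussian noise
shaped by per-second amplitude envelopes, a 1/f background, slow anti-phase
EOG excursions during B1, and sleep spindles / K-complexes injected into
every stage-C second.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .features import fft_bandpass
from .recording import EEGRecording, infer_role
from .stages import STAGE_ORDER, Stage, VigilanceTimecourse

__all__ = [
    "RegulationProfile",
    "StageSignatureModel",
    "DEFAULT_MONTAGE",
    "simulate_stage_sequence",
    "synthesize_eeg",
]

DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fz", "F3", "F4", "Cz", "Pz", "O1", "O2", "Oz", "EOG1", "EOG2",
)

#: synthesis bands (alpha is kept off the sigma band so spindle detection
#: is not confounded by alpha leakage)
_SYNTH_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.5, 11.5),
    "broadband": (1.0, 45.0),
}


@dataclass(frozen=True)
class RegulationProfile:
    """Latent arousal-regulation profile.

    ``start_level`` and the thresholds live on the MVV scale (1-6);
    ``drift_per_min`` is the mean latent decline per minute (<= 0) and
    ``volatility`` the standard deviation of the per-second latent noise.
    """

    name: str
    start_level: float
    drift_per_min: float
    volatility: float
    stage_thresholds: tuple[float, float, float, float, float] = (5.5, 4.5, 3.5, 2.5, 1.5)

    def __post_init__(self) -> None:
        thr = tuple(self.stage_thresholds)
        if len(thr) != 5 or any(b >= a for a, b in zip(thr, thr[1:])):
            raise ValueError("stage_thresholds must be 5 strictly decreasing values")
        if not all(1.0 < t < 6.0 for t in thr):
            raise ValueError("stage_thresholds must lie in (1, 6)")
        if not 1.0 <= self.start_level <= 6.0:
            raise ValueError("start_level must lie in [1, 6]")
        if self.drift_per_min > 0:
            raise ValueError("drift_per_min must be <= 0 (arousal does not trend upward)")
        if self.volatility < 0:
            raise ValueError("volatility must be >= 0")

    # -- presets -------------------------------------------------------
    @classmethod
    def hyperstable(cls, **kw) -> "RegulationProfile":
        """Rigid high arousal: expected latent stays above the 0/A1 cut for 15 min."""
        return cls("hyperstable", start_level=5.7, drift_per_min=-0.01,
                   volatility=0.25, **kw)

    @classmethod
    def adaptive(cls, **kw) -> "RegulationProfile":
        """Gradual decline from A stages toward B stages over the recording."""
        return cls("adaptive", start_level=5.3, drift_per_min=-0.18,
                   volatility=0.45, **kw)

    @classmethod
    def instable(cls, **kw) -> "RegulationProfile":
        """Immediate decline: starts below the B2/3 cut, reaches C within minutes."""
        return cls("instable", start_level=2.3, drift_per_min=-0.35,
                   volatility=0.6, **kw)


def simulate_stage_sequence(
    profile: RegulationProfile, duration_s: int, seed: int
) -> VigilanceTimecourse:
    """Draw a ground-truth per-second stage sequence from a regulation profile."""
    duration_s = int(duration_s)
    if duration_s < 60:
        raise ValueError("duration_s must be at least 60 s")
    rng = np.random.default_rng(seed)
    t_min = np.arange(duration_s) / 60.0
    latent = profile.start_level + profile.drift_per_min * t_min
    if profile.volatility > 0:
        latent = latent + rng.normal(0.0, profile.volatility, duration_s)
    thr = np.asarray(profile.stage_thresholds)
    depth = (latent[:, None] < thr[None, :]).sum(axis=1)  # 0 = stage 0 ... 5 = C
    stages = np.array([STAGE_ORDER[d] for d in depth], dtype=object)
    return VigilanceTimecourse(stages=stages)


# ----------------------------------------------------------------------
# Stage -> signal recipes
# ----------------------------------------------------------------------

def _amp(entry, region: str) -> float:
    if isinstance(entry, dict):
        return float(entry.get(region, 0.0))
    return float(entry)


@dataclass
class StageSignatureModel:
    """Spectral/event recipe turning a stage sequence into signal content.

    ``recipes[stage][band]`` is an rms amplitude in uV, either scalar (all
    regions) or a dict per region (``occipital`` / ``anterior`` / ``other``).
    ``snr`` divides the 1/f background amplitude, so large snr means clean
    stage signatures.
    """

    recipes: dict = field(default_factory=lambda: _default_recipes())
    sem_rate: float = 1.0            # SEM coverage probability per B1 second
    graphoelement_rate: float = 1.0  # expected events per C second (>= 1)
    spindle_fraction: float = 0.5    # spindle vs K-complex mix in C
    background_uV: float = 5.0       # 1/f background rms at snr = 1
    snr: float = 4.0
    spindle_amp_uV: float = 25.0     # envelope peak
    spindle_freq_hz: float = 13.5
    kcomplex_pp_uV: float = 120.0
    artifact_amp_uV: float = 150.0   # amplitude of injected artifact segments

    def amp(self, stage: Stage, band: str, region: str) -> float:
        return _amp(self.recipes.get(stage, {}).get(band, 0.0), region)

    def validate(self) -> None:
        """Enforce the qualitative stage signatures the classifier relies on."""
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        a1_occ = self.amp(Stage.A1, "alpha", "occipital")
        a1_ant = self.amp(Stage.A1, "alpha", "anterior")
        if not a1_occ > a1_ant:
            raise ValueError("A1 recipe must have occipital alpha > anterior alpha")
        a23_occ = self.amp(Stage.A23, "alpha", "occipital")
        a23_ant = self.amp(Stage.A23, "alpha", "anterior")
        if a23_ant < a23_occ:
            raise ValueError("A2/3 recipe must reverse or equalize the alpha ratio")
        if a23_occ + a23_ant >= a1_occ + a1_ant:
            raise ValueError("A2/3 recipe must have reduced total alpha vs A1")
        for region in ("occipital", "anterior"):
            td = (self.amp(Stage.B23, "theta", region) ** 2
                  + self.amp(Stage.B23, "delta", region) ** 2)
            if td <= self.amp(Stage.B23, "alpha", region) ** 2:
                raise ValueError("B2/3 recipe must be theta/delta dominated")
        if self.graphoelement_rate < 1.0:
            raise ValueError("stage C must emit >= 1 graphoelement per second "
                             "in expectation (graphoelement_rate >= 1)")


def _default_recipes() -> dict:
    occ_ant = lambda o, a, c: {"occipital": o, "anterior": a, "other": c}
    return {
        Stage.ZERO: {"delta": 2.0, "theta": 2.5, "alpha": 2.0, "broadband": 5.0},
        Stage.A1: {"delta": 4.0, "theta": 4.0,
                   "alpha": occ_ant(18.0, 6.0, 9.0), "broadband": 3.0},
        Stage.A23: {"delta": 4.0, "theta": 5.0,
                    "alpha": occ_ant(7.0, 12.0, 9.0), "broadband": 4.0},
        Stage.B1: {"delta": 2.5, "theta": 3.5, "alpha": 2.0, "broadband": 7.0},
        Stage.B23: {"delta": 14.0, "theta": 14.0, "alpha": 3.0, "broadband": 3.0},
        Stage.C: {"delta": 6.0, "theta": 8.0, "alpha": 2.0, "broadband": 3.0},
        Stage.ARTIFACT: {"broadband": 5.0},
    }


# ----------------------------------------------------------------------
# Signal synthesis
# ----------------------------------------------------------------------

def _unit_band_noise(rng, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    x = fft_bandpass(rng.standard_normal(n), fs, lo, hi)
    r = float(np.sqrt(np.mean(x**2)))
    return x / r if r > 0 else x


def _pink_noise(rng, n: int, fs: float) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))
    shaping[f > 45.0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    return x / float(np.sqrt(np.mean(x**2)))


def _hann(n: int) -> np.ndarray:
    return 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1))


def synthesize_eeg(
    stages,
    signature: Optional[StageSignatureModel] = None,
    montage: Optional[Sequence[str]] = None,
    fs: float = 250.0,
    seed: int = 0,
) -> EEGRecording:
    """Synthesize a multichannel EEG recording following a stage sequence.

    ``stages`` is a :class:`VigilanceTimecourse` (1-s epochs) or any sequence
    of stage labels, one per second.  The ground-truth timecourse and the list
    of injected events are stored on the returned recording.
    """
    tc = stages if isinstance(stages, VigilanceTimecourse) \
        else VigilanceTimecourse.from_labels(stages)
    if abs(tc.epoch_s - 1.0) > 1e-12:
        raise ValueError("synthesis expects 1-s epochs")
    signature = signature or StageSignatureModel()
    signature.validate()
    montage = list(montage or DEFAULT_MONTAGE)
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    spe = int(round(fs))
    if abs(spe - fs) > 1e-9:
        raise ValueError("fs must be an integer number of samples per second")
    roles = [infer_role(n) for n in montage]
    for region in ("occipital", "anterior"):
        if region not in roles:
            raise ValueError(f"montage lacks a required {region} channel "
                             f"(e.g. {'Oz' if region == 'occipital' else 'Fz'})")
    labels = tc.stages
    has_b1 = any(s is Stage.B1 for s in labels)
    n_eog = roles.count("eog")
    if has_b1 and n_eog == 0:
        raise ValueError("stage B1 requested but montage has no EOG channel "
                         "(add e.g. 'EOG1'/'EOG2')")

    n_sec = tc.n_epochs
    n = n_sec * spe
    rng = np.random.default_rng(seed)
    smooth_w = max(int(0.2 * fs), 1)
    data = np.zeros((len(montage), n))
    events: list[dict] = []

    # spectral content per EEG channel
    for ch, (name, region) in enumerate(zip(montage, roles)):
        if region == "eog":
            data[ch] = 2.0 * _pink_noise(rng, n, fs)
            continue
        x = np.zeros(n)
        for band, (lo, hi) in _SYNTH_BANDS.items():
            amps = np.array([signature.amp(s, band, region) for s in labels])
            if not amps.any():
                continue
            env = uniform_filter1d(np.repeat(amps, spe), smooth_w)
            x += _unit_band_noise(rng, n, fs, lo, hi) * env
        x += (signature.background_uV / signature.snr) * _pink_noise(rng, n, fs)
        data[ch] = x

    eeg_ch = [i for i, r in enumerate(roles) if r != "eog"]
    event_weight = {
        "spindle": {"occipital": 0.6, "anterior": 0.8, "other": 1.0},
        "kcomplex": {"occipital": 0.6, "anterior": 1.0, "other": 0.9},
    }

    # graphoelements in stage-C seconds (>= 1 event per second by construction)
    t = np.arange(n) / fs
    n_events_per_sec = max(1, int(round(signature.graphoelement_rate)))
    for sec, s in enumerate(labels):
        if s is not Stage.C:
            continue
        for _ in range(n_events_per_sec):
            kind = "spindle" if rng.random() < signature.spindle_fraction else "kcomplex"
            # events are confined to their second so stage labels stay crisp
            if kind == "spindle":
                wl = int(rng.uniform(0.5, 1.0) * fs)
                tau = np.arange(wl) / fs
                w = (signature.spindle_amp_uV * _hann(wl)
                     * np.sin(2 * np.pi * signature.spindle_freq_hz * tau))
                onset = sec * spe + int(rng.uniform(0, max(spe - wl, 1)))
            else:
                dur = rng.uniform(0.7, 0.9)
                wl = int(dur * fs)
                tau = np.arange(wl) / wl
                w = np.sin(2 * np.pi * tau) * _hann(wl)
                w *= signature.kcomplex_pp_uV / (w.max() - w.min())
                onset = sec * spe + int(rng.uniform(0.05, 0.95 - dur) * fs)
            onset = int(np.clip(onset, 0, n - wl - 1))
            for ch in eeg_ch:
                data[ch, onset:onset + wl] += w * event_weight[kind][roles[ch]]
            events.append({"second": sec, "kind": kind, "onset_s": onset / fs,
                           "duration_s": wl / fs})

    # slow eye movements during B1
    if n_eog:
        gate_sec = np.array(
            [1.0 if (s is Stage.B1 and rng.random() < signature.sem_rate) else 0.0
             for s in labels]
        )
        # a SEM outlasts a 1-s epoch: dilate the gate by +-0.5 s, then ramp
        gate = np.repeat(gate_sec, spe)
        gate = (uniform_filter1d(gate, max(int(1.0 * fs), 1)) > 1e-9).astype(float)
        env = uniform_filter1d(gate, max(int(0.3 * fs), 1))
        phase = rng.uniform(0, 2 * np.pi)
        wave = 60.0 * env * np.sin(2 * np.pi * 0.3 * t + phase)
        eog_ch = [i for i, r in enumerate(roles) if r == "eog"]
        data[eog_ch[0]] += wave
        if len(eog_ch) > 1:
            data[eog_ch[1]] -= wave

    # injected artifact seconds: high-amplitude square bursts
    for sec, s in enumerate(labels):
        if s is Stage.ARTIFACT:
            sl = slice(sec * spe, (sec + 1) * spe)
            data[:, sl] = signature.artifact_amp_uV * np.sign(
                np.sin(2 * np.pi * 5.0 * t[sl] + 1e-9)
            )

    return EEGRecording(
        data=data, fs=fs, ch_names=montage, roles=roles, ground_truth=tc,
        meta={"seed": int(seed), "events": events},
    )
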