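"""Per-1-s-segment features feeding the vigilance stage classifier.

For every 1-s epoch we compute, per region (occipital / anterior / other):
absolute band powers (delta 1-4, theta 4-8, alpha 8-13, sigma 12-16 Hz, in
uV^2), total 1-30 Hz power, the alpha share of total power, and from them the
*anteriorization index* (anterior alpha power / occipital alpha power) that
separates stage A1 from A2/3.  On top of the spectra come event flags: slow
eye movements (EOG), sleep spindles, K-complexes, and an artifact mask.

The spectral estimator is a Hann-windowed periodogram per epoch (epochs are
exactly one second, so a single taper is appropriate); band powers are the
integral of the one-sided PSD over the band and are Parseval-consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .recording import EEGRecording

__all__ = [
    "BANDS",
    "TOTAL_BAND",
    "EpochFeatures",
    "segment_epochs",
    "band_powers",
    "detect_sem",
    "detect_graphoelements",
    "mark_artifacts",
    "extract_features",
    "features_frame",
]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "sigma": (12.0, 16.0),
}
TOTAL_BAND: tuple[float, float] = (1.0, 30.0)

# detector defaults
ARTIFACT_UV = 100.0          # absolute amplitude bound per EEG channel
SEM_BAND = (0.1, 1.0)        # Hz, slow-eye-movement band
SEM_AMP_UV = 30.0            # minimal excursion amplitude
SEM_MIN_DUR_S = 1.0
SPINDLE_BAND = (12.0, 16.0)
SPINDLE_K = 3.0              # envelope threshold, multiples of background
SPINDLE_MIN_DUR_S = 0.4
KCOMPLEX_PP_UV = 75.0        # peak-to-peak bound on the <2.5 Hz component
KCOMPLEX_LP_HZ = 2.5


@dataclass
class EpochFeatures:
    """Spectral and event features of one 1-s segment."""

    index: int
    bp: dict                     # band -> region -> power (uV^2)
    total: dict                  # region -> 1-30 Hz power (uV^2)
    alpha_share: dict            # region -> alpha / total, in [0, 1]
    anteriorization: float       # anterior alpha / occipital alpha (inf if occ ~ 0)
    rms: float                   # mean EEG-channel rms amplitude (uV)
    sem: Optional[bool]          # None = no EOG available
    spindle: bool
    kcomplex: bool
    artifact: bool

    @property
    def best_alpha_share(self) -> float:
        return max(self.alpha_share.values())

    @property
    def best_alpha_power(self) -> float:
        return max(self.bp["alpha"].values())

    def theta_delta_share(self) -> float:
        """(delta+theta) / total 1-30 Hz power, averaged over scalp regions."""
        td = np.mean([self.bp["delta"][r] + self.bp["theta"][r] for r in self.total])
        tot = np.mean([self.total[r] for r in self.total])
        return float(td / tot) if tot > 0 else 0.0


def segment_epochs(rec: EEGRecording, epoch_s: float = 1.0) -> np.ndarray:
    """Split a recording into non-overlapping epochs.

    Returns an array of shape ``(n_epochs, n_channels, samples_per_epoch)``;
    trailing partial samples are dropped (floor rule).
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    spe = int(round(epoch_s * rec.fs))
    if spe <= 0 or rec.n_samples < spe:
        raise ValueError(
            f"recording ({rec.duration_s:.3f} s) shorter than one epoch ({epoch_s:g} s)"
        )
    n_ep = rec.n_samples // spe
    trimmed = rec.data[:, : n_ep * spe]
    return trimmed.reshape(rec.n_channels, n_ep, spe).transpose(1, 0, 2)


def band_powers(
    epoch: np.ndarray,
    fs: float,
    roles: Sequence[str],
    bands: dict | None = None,
) -> dict:
    """Per-region absolute band powers for one epoch.

    ``epoch`` is ``(n_channels, n_samples)``.  Powers are integrals of the
    Hann periodogram over each band (uV^2), averaged over the channels of each
    region; ``total`` covers 1-30 Hz.  Bands beyond Nyquist are rejected.
    """
    bands = dict(bands or BANDS)
    bands["total"] = TOTAL_BAND
    nyq = fs / 2.0
    for name, (lo, hi) in bands.items():
        if hi > nyq or lo < 0 or lo >= hi:
            raise ValueError(f"band {name} = ({lo}, {hi}) outside (0, {nyq}) Hz")
    freqs, psd = sps.periodogram(epoch, fs=fs, window="hann", detrend=False, axis=-1)
    out: dict = {name: {} for name in bands}
    for region in ("occipital", "anterior", "other"):
        ch = [i for i, r in enumerate(roles) if r == region]
        if not ch:
            continue
        p = psd[ch].mean(axis=0)
        df = freqs[1] - freqs[0]
        for name, (lo, hi) in bands.items():
            sel = (freqs >= lo) & (freqs < hi)
            out[name][region] = float(p[sel].sum() * df)
    return out


# ----------------------------------------------------------------------
# FFT band filtering helpers (shared with the synthesizer)
# ----------------------------------------------------------------------

def fft_bandpass(x: np.ndarray, fs: float, lo: float, hi: float,
                 edge: float = 0.25) -> np.ndarray:
    """Zero-phase band-pass via FFT masking with raised-cosine edges."""
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = np.ones_like(freqs)
    if lo > 0:
        mask *= np.clip((freqs - (lo - edge)) / (2 * edge), 0.0, 1.0)
    mask *= np.clip(((hi + edge) - freqs) / (2 * edge), 0.0, 1.0)
    mask = 0.5 - 0.5 * np.cos(np.pi * np.clip(mask, 0, 1))  # soften
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * mask, n=n, axis=-1)


def _runs_at_least(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Boolean per-sample array marking membership in a True-run >= min_len."""
    if mask.size == 0:
        return mask
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts, ends = np.where(d == 1)[0], np.where(d == -1)[0]
    out = np.zeros_like(mask)
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            out[s:e] = True
    return out


# ----------------------------------------------------------------------
# Event detectors
# ----------------------------------------------------------------------

def detect_sem(
    eog: np.ndarray,
    fs: float,
    amp_uV: float = SEM_AMP_UV,
    band: tuple[float, float] = SEM_BAND,
    min_dur_s: float = SEM_MIN_DUR_S,
) -> Optional[bool]:
    """Detect a slow horizontal eye movement in an EOG window.

    ``eog`` is ``(n_eog_channels, n_samples)`` and should span the epoch of
    interest plus ~1 s of context on each side (a SEM outlasts one epoch).
    Returns ``None`` ("unavailable") when no EOG channel is given — never a
    silent False.  With two channels the anti-phase difference signal is used,
    which doubles SEM amplitude and cancels common-mode drift.
    """
    eog = np.atleast_2d(np.asarray(eog, dtype=float))
    if eog.size == 0 or eog.shape[0] == 0:
        return None
    if eog.shape[0] >= 2:
        x = (eog[0] - eog[1]) / 2.0
    else:
        x = eog[0]
    xf = fft_bandpass(x, fs, band[0], band[1])
    if np.max(np.abs(xf)) < amp_uV:
        return False
    sustained = _runs_at_least(np.abs(xf) >= amp_uV / 2.0, int(min_dur_s * fs))
    return bool(sustained.any())


def detect_graphoelements(
    window: np.ndarray,
    fs: float,
    sigma_background: Optional[float] = None,
    spindle_k: float = SPINDLE_K,
    kcomplex_pp_uV: float = KCOMPLEX_PP_UV,
) -> tuple[bool, bool]:
    """Detect sleep spindles and K-complexes in an EEG window.

    ``window`` is ``(n_channels, n_samples)`` and may exceed one second;
    ``sigma_background`` is the background sigma-envelope level (uV).  When
    not given it is estimated as the 25th percentile of the window's own
    envelope (prefer passing the recording-wide estimate).

    A spindle requires the mean sigma-band (12-16 Hz) Hilbert envelope to stay
    above ``spindle_k`` times background for >= 0.4 s.  A K-complex requires a
    biphasic < 2.5 Hz transient with peak-to-peak >= 75 uV and both polarities
    expressed.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    sig = fft_bandpass(window, fs, *SPINDLE_BAND)
    env = np.abs(sps.hilbert(sig, axis=-1)).mean(axis=0)
    bg = float(np.percentile(env, 25)) if sigma_background is None else sigma_background
    bg = max(bg, 1e-12)
    spindle = bool(_runs_at_least(env >= spindle_k * bg,
                                  int(SPINDLE_MIN_DUR_S * fs)).any())

    slow = fft_bandpass(window, fs, 0.0, KCOMPLEX_LP_HZ).mean(axis=0)
    pp = float(slow.max() - slow.min())
    kcomplex = bool(pp >= kcomplex_pp_uV and slow.max() >= 0.3 * kcomplex_pp_uV
                    and slow.min() <= -0.3 * kcomplex_pp_uV)
    return spindle, kcomplex


def mark_artifacts(epoch: np.ndarray, threshold_uV: float = ARTIFACT_UV) -> bool:
    """Artifact mask for one EEG epoch: amplitude beyond +-threshold or a flat channel."""
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.size == 0:
        return True
    if np.any(np.abs(epoch) > threshold_uV):
        return True
    ptp = epoch.max(axis=-1) - epoch.min(axis=-1)
    return bool(np.any(ptp < 1e-9))


# ----------------------------------------------------------------------
# Batch extraction
# ----------------------------------------------------------------------

def extract_features(
    rec: EEGRecording,
    epoch_s: float = 1.0,
    artifact_uV: float = ARTIFACT_UV,
    spindle_k: float = SPINDLE_K,
) -> list[EpochFeatures]:
    """Compute :class:`EpochFeatures` for every epoch of a recording.

    Recording-wide quantities (sigma-envelope background for spindles, the
    band-pass filtered EOG/slow traces) are computed once, then evaluated per
    epoch; this is the canonical path used by the stage classifier.
    """
    rec.validate_montage()
    fs = rec.fs
    spe = int(round(epoch_s * fs))
    epochs = segment_epochs(rec, epoch_s)
    n_ep = epochs.shape[0]
    eeg = rec.eeg_idx
    eeg_roles = [rec.roles[i] for i in eeg]

    # recording-wide filtered traces
    eeg_data = rec.data[eeg, : n_ep * spe]
    sig = fft_bandpass(eeg_data, fs, *SPINDLE_BAND)
    env = np.abs(sps.hilbert(sig, axis=-1)).mean(axis=0)
    sigma_bg = max(float(np.percentile(env, 25)), 1e-12)
    spindle_mask = _runs_at_least(env >= spindle_k * sigma_bg, int(SPINDLE_MIN_DUR_S * fs))
    slow = fft_bandpass(eeg_data, fs, 0.0, KCOMPLEX_LP_HZ).mean(axis=0)

    eog = rec.eog_idx
    if eog.size:
        eog_data = rec.data[eog, : n_ep * spe]
        x = (eog_data[0] - eog_data[1]) / 2.0 if eog.size >= 2 else eog_data[0]
        eog_f = fft_bandpass(x, fs, *SEM_BAND)
        sem_sustained = _runs_at_least(np.abs(eog_f) >= SEM_AMP_UV / 2.0,
                                       int(SEM_MIN_DUR_S * fs))
    else:
        eog_f = sem_sustained = None

    # vectorized spectra: one periodogram over all (epoch, channel) pairs
    eeg_epochs = epochs[:, eeg, :]                      # (n_ep, n_eeg, spe)
    freqs, psd = sps.periodogram(eeg_epochs, fs=fs, window="hann",
                                 detrend=False, axis=-1)
    df = freqs[1] - freqs[0]
    all_bands = dict(BANDS)
    all_bands["total"] = TOTAL_BAND
    regions = [r for r in ("occipital", "anterior", "other")
               if r in set(eeg_roles)]
    bp_arr: dict = {}
    for region in regions:
        ch = [j for j, r in enumerate(eeg_roles) if r == region]
        p = psd[:, ch, :].mean(axis=1)                  # (n_ep, n_freq)
        for name, (lo, hi) in all_bands.items():
            sel = (freqs >= lo) & (freqs < hi)
            bp_arr[(name, region)] = p[:, sel].sum(axis=1) * df

    rms_arr = np.sqrt(np.mean(eeg_epochs**2, axis=(1, 2)))
    over = np.any(np.abs(eeg_epochs) > artifact_uV, axis=(1, 2))
    flat = np.any(eeg_epochs.max(axis=-1) - eeg_epochs.min(axis=-1) < 1e-9, axis=1)

    feats: list[EpochFeatures] = []
    kc_margin = spe // 10  # allow for low-pass smearing of K-complex tails
    for i in range(n_ep):
        a, b = i * spe, (i + 1) * spe
        bp = {name: {r: float(bp_arr[(name, r)][i]) for r in regions}
              for name in all_bands}
        alpha_share = {
            r: (bp["alpha"][r] / bp["total"][r]) if bp["total"][r] > 0 else 0.0
            for r in regions
        }
        occ_a = bp["alpha"].get("occipital", 0.0)
        ant_a = bp["alpha"].get("anterior", 0.0)
        anterior_idx = float(ant_a / occ_a) if occ_a > 1e-12 else float("inf")

        spindle = bool(spindle_mask[a:b].any())
        sl = slow[max(0, a - kc_margin): min(n_ep * spe, b + kc_margin)]
        pp = float(sl.max() - sl.min())
        kc = bool(pp >= KCOMPLEX_PP_UV and sl.max() >= 0.3 * KCOMPLEX_PP_UV
                  and sl.min() <= -0.3 * KCOMPLEX_PP_UV)

        if eog_f is None:
            sem: Optional[bool] = None
        else:
            center_hit = np.max(np.abs(eog_f[a:b])) >= SEM_AMP_UV
            sem = bool(center_hit and sem_sustained[max(0, a - spe):b + spe].any())

        feats.append(
            EpochFeatures(
                index=i,
                bp={k: bp[k] for k in BANDS},
                total=bp["total"],
                alpha_share=alpha_share,
                anteriorization=anterior_idx,
                rms=float(rms_arr[i]),
                sem=sem,
                spindle=spindle,
                kcomplex=kc,
                artifact=bool(over[i] or flat[i]),
            )
        )
    return feats


def features_frame(feats: list[EpochFeatures]) -> "pd.DataFrame":
    """Flatten a feature list into a tidy DataFrame (one row per epoch)."""
    import pandas as pd

    rows = []
    for f in feats:
        row = {"epoch": f.index, "rms": f.rms, "anteriorization": f.anteriorization,
               "sem": f.sem, "spindle": f.spindle, "kcomplex": f.kcomplex,
               "artifact": f.artifact}
        for band, per_region in f.bp.items():
            for region, v in per_region.items():
                row[f"{band}_{region}"] = v
        for region, v in f.total.items():
            row[f"total_{region}"] = v
            row[f"alpha_share_{region}"] = f.alpha_share[region]
        rows.append(row)
    return pd.DataFrame(rows)
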