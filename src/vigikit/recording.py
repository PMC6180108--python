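"""Multichannel EEG recording container plus EDF/BrainVision I/O.

Signals are held in microvolts as a ``channels x samples`` float array.
Channel *roles* drive the regional band-power features:

- ``occipital``: 10-20 names starting with ``O`` or ``PO``
- ``anterior``: names starting with ``Fp``, ``AF`` or ``F``
- ``eog``: names containing ``EOG``
- ``other``: everything else (central, parietal, temporal)

Reading goes through :mod:`mne` (EDF and BrainVision).  Writing uses a small
built-in EDF writer (16-bit, one data record per second).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .stages import VigilanceTimecourse

__all__ = ["EEGRecording", "infer_role", "read_edf", "read_brainvision", "write_edf"]

EEG_REGIONS = ("occipital", "anterior", "other")


def infer_role(name: str) -> str:
    """Infer a channel role from its 10-20 style name."""
    up = name.upper().strip()
    if "EOG" in up:
        return "eog"
    if up.startswith(("O", "PO")):
        return "occipital"
    if up.startswith(("FP", "AF", "F")):
        return "anterior"
    return "other"


@dataclass
class EEGRecording:
    """An EEG recording: samples in microvolts, channel names and roles.

    ``ground_truth`` optionally carries the true per-second stage sequence for
    synthetic recordings; ``meta`` is free-form (subject/day ids, injected
    event list, ...).
    """

    data: np.ndarray            # (n_channels, n_samples), microvolts
    fs: float
    ch_names: Sequence[str]
    roles: Optional[Sequence[str]] = None
    ground_truth: Optional[VigilanceTimecourse] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length does not match data")
        if self.roles is None:
            self.roles = [infer_role(n) for n in self.ch_names]
        self.roles = list(self.roles)
        if len(self.roles) != self.data.shape[0]:
            raise ValueError("roles length does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def idx(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)

    @property
    def eeg_idx(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r != "eog"], dtype=int)

    @property
    def eog_idx(self) -> np.ndarray:
        return self.idx("eog")

    def validate_montage(self, require_eog: bool = False) -> None:
        """Check minimal montage requirements, naming what is missing."""
        for region in ("occipital", "anterior"):
            if self.idx(region).size == 0:
                raise ValueError(f"montage lacks a required {region} EEG channel")
        if require_eog and self.eog_idx.size == 0:
            raise ValueError("montage lacks a required EOG channel")


# ----------------------------------------------------------------------
# Readers (mne-backed)
# ----------------------------------------------------------------------

def _from_raw(raw, roles=None, meta=None) -> EEGRecording:
    data = raw.get_data() * 1e6  # volts -> microvolts
    names = list(raw.ch_names)
    return EEGRecording(
        data=data, fs=float(raw.info["sfreq"]), ch_names=names,
        roles=[roles.get(n, infer_role(n)) for n in names] if roles else None,
        meta=meta or {},
    )


def read_edf(path, roles: Optional[dict] = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolts).

    ``roles`` optionally overrides the name-based channel-role inference,
    mapping channel name -> role.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return _from_raw(raw, roles, {"path": str(path)})


def read_brainvision(vhdr_path, roles: Optional[dict] = None) -> EEGRecording:
    """Read a BrainVision triplet (.vhdr/.vmrk/.eeg) into an :class:`EEGRecording`."""
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return _from_raw(raw, roles, {"path": str(vhdr_path)})


# ----------------------------------------------------------------------
# Minimal EDF writer
# ----------------------------------------------------------------------

def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", "replace")[:n]
    return b + b" " * (n - len(b))


def write_edf(rec: EEGRecording, path) -> None:
    """Write an :class:`EEGRecording` as a plain EDF file.

    16-bit encoding, one data record per second; the sampling rate must
    therefore be an integer.  Physical range is chosen per channel from the
    data (symmetric, rounded up), so quantisation error is below
    ``range / 65536``.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = rec.n_samples // fs
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_rec * fs]
    nch = rec.n_channels

    phys_max = np.maximum(np.ceil(np.max(np.abs(data), axis=1)), 1.0)
    dig_max, dig_min = 32767, -32768
    # affine mapping matching the EDF reading convention:
    # physical = (digital - dig_min) * slope + phys_min
    slope = 2.0 * phys_max / (dig_max - dig_min)

    start = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("synthetic resting EEG", 80),
            _pad(start.strftime("%d.%m.%y"), 8),
            _pad(start.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (nch + 1)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(nch), 4),
        ]
    )
    header += b"".join(_pad(str(n), 16) for n in rec.ch_names)
    header += b"".join(_pad("AgAgCl electrode", 80) for _ in range(nch))
    header += b"".join(_pad("uV", 8) for _ in range(nch))
    header += b"".join(_pad(f"{-m:g}", 8) for m in phys_max)
    header += b"".join(_pad(f"{m:g}", 8) for m in phys_max)
    header += b"".join(_pad(str(dig_min), 8) for _ in range(nch))
    header += b"".join(_pad(str(dig_max), 8) for _ in range(nch))
    header += b"".join(_pad("", 80) for _ in range(nch))
    header += b"".join(_pad(str(fs), 8) for _ in range(nch))
    header += b"".join(_pad("", 32) for _ in range(nch))

    digital = np.clip(
        np.round((data - (-phys_max[:, None])) / slope[:, None]) + dig_min,
        dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())
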