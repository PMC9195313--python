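"""Reading, resampling, re-referencing, epoching and artifact rejection.

Conventions
-----------
* Signals are microvolts, channels x samples.
* Sampling rates on ingest are 1024 or 2048 Hz; everything downstream runs at
  1024 Hz.
* Epochs span [-1.1, +1.5) s around stimulus onset.  The pre-stimulus second
  [-1.0, 0) is the ERP baseline; the full [-1.1, 0) pre-stimulus span is the
  decibel baseline for the time-frequency analysis.
* Outlier epochs (SD > 2.5x the mean epoch SD, per channel) are masked, never
  deleted, so trial bookkeeping stays intact.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from ._edf import read_edf

__all__ = [
    "ChannelInfo",
    "Recording",
    "EpochSet",
    "read_recording",
    "resample_to_1024",
    "rereference",
    "epoch",
    "reject_outlier_epochs",
    "bandpass_erp",
    "VALID_FS",
    "ERP_BASELINE",
    "DB_BASELINE",
]

VALID_FS = (1024, 2048)
ERP_BASELINE = (-1.0, 0.0)  # seconds, half-open [lo, hi)
DB_BASELINE = (-1.1, 0.0)


@dataclass(frozen=True)
class ChannelInfo:
    name: str
    region: str
    hemisphere: str
    patient: str
    group: str


@dataclass
class Recording:
    """Continuous multichannel recording with per-channel metadata."""

    data: np.ndarray  # channels x samples, µV
    fs: float
    channels: list[ChannelInfo]

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel metadata does not match data rows")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    @property
    def ch_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def pick(self, names) -> "Recording":
        idx = [self.ch_names.index(n) for n in names]
        return Recording(self.data[idx].copy(), self.fs,
                         [self.channels[i] for i in idx])


@dataclass
class EpochSet:
    """Trials x channels x time array locked to stimulus onset."""

    data: np.ndarray          # trials x channels x time, µV
    t: np.ndarray             # seconds relative to onset
    fs: float
    reference: str            # "none", "fz_monopolar" or "bipolar"
    channels: list[ChannelInfo]
    categories: np.ndarray    # per trial
    kept_mask: np.ndarray = field(default=None)  # trials x channels bool
    bad_channels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.categories = np.asarray(self.categories)
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[:2], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.kept_mask.shape != self.data.shape[:2]:
            raise ValueError("kept_mask must be trials x channels")
        if self.t.size != self.data.shape[2] or np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be sorted and match the data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def ch_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def time_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask for the half-open window [lo, hi) seconds."""
        return (self.t >= lo - 1e-12) & (self.t < hi - 1e-12)

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.t.copy(), self.fs,
                        self.reference, list(self.channels),
                        self.categories.copy(), self.kept_mask.copy(),
                        list(self.bad_channels))


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------

def read_recording(edf_path, channels_tsv, events_tsv, patient=None):
    """Read an EDF plus channel-metadata and events TSVs.

    Returns (Recording, events DataFrame).  EDF channels absent from the
    metadata table are dropped with a warning.  Event onsets must lie inside
    the recording.  ``patient`` restricts a study-wide metadata table (where
    channel labels repeat across patients) to one patient's rows.
    """
    edf_path = Path(edf_path)
    if not edf_path.exists():
        raise FileNotFoundError(str(edf_path))
    data, fs, names = read_edf(edf_path)
    if int(round(fs)) not in VALID_FS:
        raise ValueError(f"unsupported sampling rate {fs}; expected one of {VALID_FS}")

    meta = pd.read_csv(channels_tsv, sep="\t", dtype=str)
    required = {"channel", "region", "hemisphere", "patient", "group"}
    if not required.issubset(meta.columns):
        raise ValueError(f"channels TSV must have columns {sorted(required)}")
    if patient is not None:
        meta = meta[meta["patient"] == patient]
    if meta["channel"].duplicated().any():
        dup = meta.loc[meta["channel"].duplicated(), "channel"].tolist()
        raise ValueError(f"ambiguous channel metadata (duplicate labels {dup});"
                         " pass patient= to disambiguate")
    meta = meta.set_index("channel")

    keep_idx, channels = [], []
    for i, name in enumerate(names):
        if name not in meta.index:
            warnings.warn(f"EDF channel {name!r} not in metadata; dropped")
            continue
        row = meta.loc[name]
        keep_idx.append(i)
        channels.append(ChannelInfo(name, row["region"], row["hemisphere"],
                                    row["patient"], row["group"]))
    if not keep_idx:
        raise ValueError("no EDF channel matches the metadata table")
    rec = Recording(data[keep_idx], fs, channels)

    events = pd.read_csv(events_tsv, sep="\t")
    if events.empty:
        raise ValueError(f"events table {events_tsv} is empty")
    if not {"onset_s", "category"}.issubset(events.columns):
        raise ValueError("events TSV must have columns onset_s, category")
    if not np.all(np.diff(events["onset_s"].to_numpy()) > 0):
        raise ValueError("event onsets must be strictly increasing")
    if (events["onset_s"].max() >= rec.duration) or (events["onset_s"].min() < 0):
        raise ValueError("event onset outside recording")
    return rec, events.reset_index(drop=True)


# ---------------------------------------------------------------------------
# resampling / referencing
# ---------------------------------------------------------------------------

def resample_to_1024(rec: Recording) -> Recording:
    """Decimate 2048 Hz recordings to 1024 Hz with a linear-phase FIR
    anti-alias filter; 1024 Hz input passes through unchanged."""
    fs = int(round(rec.fs))
    if fs == 1024:
        return Recording(rec.data.copy(), 1024.0, list(rec.channels))
    if fs != 2048:
        raise ValueError(f"unsupported sampling rate {rec.fs}")
    # pass to ~460 Hz, stop by the new Nyquist (512 Hz); odd-length symmetric
    # taps applied via 'same' convolution => zero phase
    taps = signal.firwin(255, 480.0, fs=2048.0)
    filt = signal.fftconvolve(rec.data, taps[None, :], mode="same", axes=1)
    return Recording(filt[:, ::2], 1024.0, list(rec.channels))


def rereference(rec: Recording, mode: str) -> Recording:
    """Re-reference either against scalp Fz (monopolar) or as adjacent-contact
    bipolar derivations within each (patient, region, hemisphere) electrode."""
    names = rec.ch_names
    if mode == "fz_monopolar":
        fz_idx = [i for i, c in enumerate(rec.channels)
                  if c.name == "Fz" or c.region == "scalp-Fz"]
        if not fz_idx:
            raise ValueError("fz_monopolar reference requires a channel named Fz")
        fz = rec.data[fz_idx[0]]
        keep = [i for i in range(len(names)) if i not in fz_idx]
        data = rec.data[keep] - fz[None, :]
        return Recording(data, rec.fs, [rec.channels[i] for i in keep])

    if mode == "bipolar":
        groups: dict[tuple, list[int]] = {}
        for i, c in enumerate(rec.channels):
            if c.region == "scalp-Fz":
                continue
            groups.setdefault((c.patient, c.region, c.hemisphere), []).append(i)

        def contact_number(name: str) -> int:
            digits = "".join(ch for ch in name if ch.isdigit())
            return int(digits) if digits else 0

        rows, channels = [], []
        for key, idx in groups.items():
            idx = sorted(idx, key=lambda i: contact_number(rec.channels[i].name))
            if len(idx) < 2:
                warnings.warn(
                    f"singleton contact group {key} dropped from bipolar reference")
                continue
            for a, b in zip(idx[:-1], idx[1:]):
                ca, cb = rec.channels[a], rec.channels[b]
                rows.append(rec.data[a] - rec.data[b])
                channels.append(ChannelInfo(f"{ca.name}-{cb.name}", ca.region,
                                            ca.hemisphere, ca.patient, ca.group))
        if not rows:
            raise ValueError("no electrode group has >= 2 contacts for bipolar reference")
        return Recording(np.vstack(rows), rec.fs, channels)

    raise ValueError(f"unknown reference mode {mode!r}")


# ---------------------------------------------------------------------------
# epoching / rejection / filtering
# ---------------------------------------------------------------------------

def epoch(rec: Recording, events: pd.DataFrame, tmin: float = -1.1,
          tmax: float = 1.5, reference: str = "none") -> EpochSet:
    """Cut trials around stimulus onsets.

    t = 0 is the first sample at or after the onset; windows are half-open
    [tmin, tmax).
    """
    fs = rec.fs
    n_pre = int(round(-tmin * fs))
    n_post = int(round(tmax * fs))
    t = np.arange(-n_pre, n_post) / fs
    onsets = np.asarray(events["onset_s"], dtype=float)
    i0 = np.ceil(onsets * fs - 1e-9).astype(int)
    starts, stops = i0 - n_pre, i0 + n_post
    bad = np.nonzero((starts < 0) | (stops > rec.data.shape[1]))[0]
    if bad.size:
        raise ValueError(
            "events outside recording (rows "
            + ", ".join(map(str, bad.tolist())) + ")")
    data = np.stack([rec.data[:, a:b] for a, b in zip(starts, stops)])
    return EpochSet(data, t, fs, reference, list(rec.channels),
                    events["category"].to_numpy())


def reject_outlier_epochs(ep: EpochSet, factor: float = 2.5) -> EpochSet:
    """Mask epochs whose SD exceeds ``factor`` x the mean epoch SD.

    The SD is taken over the full epoch span; the criterion is evaluated
    independently per channel, over all trials of that channel.
    """
    if ep.n_trials < 2:
        raise ValueError("need at least 2 trials for outlier rejection")
    out = ep.copy()
    sd = ep.data.std(axis=2)                  # trials x channels
    mean_sd = sd.mean(axis=0, keepdims=True)  # per channel
    out.kept_mask = ep.kept_mask & (sd <= factor * mean_sd)
    dead = np.nonzero(~out.kept_mask.any(axis=0))[0]
    for i in dead:
        name = ep.channels[i].name
        if name not in out.bad_channels:
            out.bad_channels.append(name)
            warnings.warn(f"all trials rejected on channel {name}; flagged unusable")
    return out


def bandpass_erp(ep: EpochSet, lo: float = 0.5, hi: float = 20.0) -> EpochSet:
    """Zero-phase 0.5-20 Hz band-pass for the ERP path (4th-order Butterworth,
    forward-backward)."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=ep.fs, output="sos")
    out = ep.copy()
    out.data = signal.sosfiltfilt(sos, ep.data, axis=2)
    return out
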