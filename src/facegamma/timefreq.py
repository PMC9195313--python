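"""Induced-power analysis: ERP subtraction, Morlet decomposition, decibel
baselining and windowed gamma-band extraction.

The decomposition uses 40 logarithmically spaced frequencies from 1 to 200 Hz
with wavelet widths increasing logarithmically from 3 cycles (1 Hz) to 10
cycles (200 Hz).  Convolution is FFT-based on reflect-padded epochs; samples
closer to an epoch edge than the wavelet half-width are flagged as
edge-contaminated and never enter baselines or measurement windows.

Decibel baselining divides by a per-(channel, frequency) baseline B(f) taken
from the pre-stimulus [-1.1, 0) span of the *trial-averaged* power map; B(f)
is the geometric mean over baseline samples, which makes the trial-averaged
dB map average to exactly zero over the baseline span.  Per-trial dB values
(for the trial-level mixed models) use the same common B(f).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .io_preprocess import DB_BASELINE, EpochSet

__all__ = ["log_freqs", "log_cycles", "morlet_complex", "subtract_erp",
           "morlet_power", "baseline_db", "window_gamma_power", "TimeFreqMap",
           "GAMMA_BAND", "EARLY_WINDOW", "LATE_WINDOW", "WINDOW_BY_REGION",
           "average_trials"]

GAMMA_BAND = (45.0, 150.0)
EARLY_WINDOW = (0.0, 0.750)   # s, half-open; amygdala / fusiform / parahippocampal
LATE_WINDOW = (0.250, 1.000)  # s; hippocampus
WINDOW_BY_REGION = {"amygdala": EARLY_WINDOW, "fusiform": EARLY_WINDOW,
                    "parahippocampal": EARLY_WINDOW, "hippocampus": LATE_WINDOW}


def log_freqs(n: int = 40, fmin: float = 1.0, fmax: float = 200.0) -> np.ndarray:
    """Logarithmically spaced analysis frequencies (constant ratio)."""
    return np.logspace(np.log10(fmin), np.log10(fmax), n)


def log_cycles(freqs, c_lo: float = 3.0, c_hi: float = 10.0) -> np.ndarray:
    """Wavelet widths in cycles, log-increasing across the frequency axis."""
    freqs = np.asarray(freqs, dtype=float)
    lo, hi = freqs[0], freqs[-1]
    return c_lo * (c_hi / c_lo) ** (np.log(freqs / lo) / np.log(hi / lo))


@dataclass
class TimeFreqMap:
    power: np.ndarray          # trials x channels x freqs x time
    freqs: np.ndarray
    t: np.ndarray
    fs: float
    units: str                 # "uV^2" or "dB"
    channels: list
    categories: np.ndarray
    kept_mask: np.ndarray      # trials x channels
    edge_mask: np.ndarray      # freqs x time, True where edge-contaminated
    baseline_span: tuple = None

    def copy_with(self, **kw):
        d = dict(power=self.power, freqs=self.freqs, t=self.t, fs=self.fs,
                 units=self.units, channels=self.channels,
                 categories=self.categories, kept_mask=self.kept_mask,
                 edge_mask=self.edge_mask, baseline_span=self.baseline_span)
        d.update(kw)
        return TimeFreqMap(**d)

    def time_mask(self, lo, hi):
        return (self.t >= lo - 1e-12) & (self.t < hi - 1e-12)


def subtract_erp(ep: EpochSet) -> EpochSet:
    """Remove the phase-locked component: subtract each channel's kept-trial
    average from every epoch of that channel."""
    out = ep.copy()
    mask = ep.kept_mask.astype(float)
    n = mask.sum(axis=0)
    n = np.where(n > 0, n, 1.0)
    avg = np.einsum("ict,ic->ct", ep.data, mask) / n[:, None]
    out.data = ep.data - avg[None, :, :]
    return out


def _wavelet(f: float, n_cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet, unit gain for a pure sinusoid at its centre frequency:
    |coefficient| equals the sinusoid's amplitude."""
    sigma_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * f * t) * np.exp(-0.5 * (t / sigma_t) ** 2)
    gain = np.abs(np.sum(w * np.exp(-2j * np.pi * f * t)))  # envelope sum
    return w * (2.0 / gain)


def morlet_complex(data: np.ndarray, fs: float, freqs, n_cycles=None,
                   decim: int = 1):
    """Complex Morlet coefficients of ``data`` (... x time).

    Returns (coefs: freqs x ... x time/decim, edge_mask: freqs x time/decim).
    Epochs are reflect-padded by each wavelet's half-width before FFT
    convolution.
    """
    data = np.asarray(data, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if n_cycles is None:
        n_cycles = log_cycles(freqs)
    n_cycles = np.broadcast_to(np.asarray(n_cycles, dtype=float), freqs.shape)
    n_t = data.shape[-1]
    out_t = len(range(0, n_t, decim))
    coefs = np.empty((freqs.size,) + data.shape[:-1] + (out_t,),
                     dtype=np.complex128)
    edge = np.zeros((freqs.size, out_t), dtype=bool)
    idx_full = np.arange(n_t)[::decim]
    for i, (f, nc) in enumerate(zip(freqs, n_cycles)):
        w = _wavelet(f, nc, fs)
        half = (w.size - 1) // 2
        pad = min(half, n_t - 1)
        padded = np.concatenate(
            [data[..., 1:pad + 1][..., ::-1], data,
             data[..., -pad - 1:-1][..., ::-1]], axis=-1)
        conv = fftconvolve(padded, w.reshape((1,) * (data.ndim - 1) + (-1,)),
                           mode="same", axes=-1)
        coefs[i] = conv[..., pad:pad + n_t][..., ::decim]
        edge[i] = (idx_full < half) | (idx_full >= n_t - half)
    return coefs, edge


def morlet_power(ep: EpochSet, freqs=None, n_cycles=None,
                 decim: int = 1) -> TimeFreqMap:
    """Single-trial wavelet power (µV²) over the 40-frequency log axis."""
    if freqs is None:
        freqs = log_freqs()
    coefs, edge = morlet_complex(ep.data, ep.fs, freqs, n_cycles, decim)
    # freqs x trials x channels x time -> trials x channels x freqs x time
    power = np.moveaxis((coefs.real ** 2 + coefs.imag ** 2), 0, 2)
    power = power.astype(np.float32)
    sigma_lo = (n_cycles[0] if n_cycles is not None else log_cycles(freqs)[0]) \
        / (2 * np.pi * freqs[0])
    if 3.0 * sigma_lo * ep.fs > ep.data.shape[-1]:
        warnings.warn("epoch shorter than 3 wavelet SDs at the lowest "
                      "frequency; low-frequency bins are edge-contaminated")
    return TimeFreqMap(power, np.asarray(freqs, float), ep.t[::decim].copy(),
                       ep.fs / decim, "uV^2", list(ep.channels),
                       ep.categories.copy(), ep.kept_mask.copy(), edge)


def average_trials(tf: TimeFreqMap, subset=None) -> TimeFreqMap:
    """Average power over kept trials (optionally restricted to categories);
    result has a singleton trial axis."""
    sel = np.ones(tf.power.shape[0], dtype=bool)
    if subset is not None:
        subset = (subset,) if isinstance(subset, str) else tuple(subset)
        sel = np.isin(tf.categories, subset)
        if not sel.any():
            raise ValueError(f"no trials in categories {subset}")
    mask = (tf.kept_mask & sel[:, None]).astype(np.float64)
    n = mask.sum(axis=0)
    if (n == 0).any():
        raise ValueError("channel with no kept trials in subset")
    avg = np.einsum("icft,ic->cft", tf.power.astype(np.float64), mask) / n[:, None, None]
    return tf.copy_with(power=avg[None], categories=np.asarray(["average"]),
                        kept_mask=np.ones((1, len(tf.channels)), bool))


def baseline_db(tf: TimeFreqMap, span=DB_BASELINE) -> TimeFreqMap:
    """Convert to decibels relative to the pre-stimulus baseline.

    B(f) per channel is the geometric mean over baseline samples of the
    kept-trial-averaged power, so the trial-averaged dB map has exactly zero
    mean over the baseline span.  Edge-contaminated samples are excluded from
    the baseline.
    """
    if tf.units != "uV^2":
        raise ValueError("baseline_db expects a raw-power map")
    base_t = tf.time_mask(*span)
    power = tf.power.astype(np.float64)
    if power.shape[0] == 1:
        avg = power[0]
    else:
        mask = tf.kept_mask.astype(np.float64)
        n = np.where(mask.sum(axis=0) > 0, mask.sum(axis=0), 1.0)
        avg = np.einsum("icft,ic->cft", power, mask) / n[:, None, None]
    if (avg[:, :, base_t] <= 0).any():
        raise ValueError("nonpositive baseline power")
    # geometric mean over every baseline sample: the trial-averaged dB map
    # then averages to exactly zero over the baseline span
    log_b = np.log10(avg[:, :, base_t]).mean(axis=2)  # channels x freqs
    with np.errstate(divide="ignore"):
        db = 10.0 * (np.log10(power) - log_b[None, :, :, None])
    return tf.copy_with(power=db.astype(np.float32), units="dB",
                        baseline_span=tuple(span))


def window_gamma_power(tf: TimeFreqMap, band=GAMMA_BAND,
                       windows=WINDOW_BY_REGION) -> pd.DataFrame:
    """Trial-level mean gamma power rows for the mixed models.

    Per kept trial x channel: the 45-150 Hz x region-window block of the dB
    map is converted back to power ratios, averaged, and re-expressed in dB
    (log of the mean ratio, which avoids the single-trial log bias).
    Hippocampal channels use the late 250-1000 ms window, the other regions
    the early 0-750 ms window.
    """
    if tf.units != "dB":
        raise ValueError("window_gamma_power expects a dB map")
    fmask = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    rows = []
    for ci, ch in enumerate(tf.channels):
        if ch.region not in windows:
            raise ValueError(f"unknown region {ch.region!r}")
        lo, hi = windows[ch.region]
        tmask = tf.time_mask(lo, hi)
        block = tf.power[:, ci][:, fmask][:, :, tmask].astype(np.float64)
        vals = 10.0 * np.log10(np.mean(10.0 ** (block / 10.0), axis=(1, 2)))
        for ti in np.nonzero(tf.kept_mask[:, ci])[0]:
            rows.append((ch.patient, ch.group, ch.hemisphere, ch.region,
                         ch.name, int(ti), tf.categories[ti]
                         if tf.categories.size > 1 else tf.categories[0],
                         vals[ti]))
    return pd.DataFrame(rows, columns=["patient", "group", "hemisphere",
                                       "region", "channel", "trial",
                                       "category", "gamma_db"])
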