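"""Event-related potentials and trial-level peak-window amplitudes.

ERPs are averages over kept trials of baseline-corrected epochs.  The baseline
is the per-trial mean over the pre-stimulus second [-1.0, 0); correction is
applied per trial so that trial-level amplitudes feed directly into the
mixed-effects models.  Outputs are sign-flipped (x -1) so that the negative
deflections N110/N240/N360 plot and tabulate as positive values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_preprocess import ERP_BASELINE, EpochSet

__all__ = ["PeakWindow", "PEAK_WINDOWS", "ERPWaveform", "compute_erp",
           "trial_peak_amplitudes"]


@dataclass(frozen=True)
class PeakWindow:
    """An 80-ms measurement window centred on a nominal peak latency."""

    name: str
    center_ms: float
    half_width_ms: float = 40.0

    @property
    def bounds_s(self):
        return ((self.center_ms - self.half_width_ms) / 1000.0,
                (self.center_ms + self.half_width_ms) / 1000.0)


PEAK_WINDOWS = (PeakWindow("N110", 110.0),
                PeakWindow("N240", 240.0),
                PeakWindow("N360", 360.0))


@dataclass
class ERPWaveform:
    mean: np.ndarray      # channels x time, display sign (raw x -1), µV
    n_trials: np.ndarray  # kept-trial count per channel
    t: np.ndarray
    channels: list


def _baseline_corrected(ep: EpochSet) -> np.ndarray:
    base = ep.time_mask(*ERP_BASELINE)
    return ep.data - ep.data[:, :, base].mean(axis=2, keepdims=True)


def _select_trials(ep: EpochSet, subset):
    if subset is None:
        return np.ones(ep.n_trials, dtype=bool)
    subset = (subset,) if isinstance(subset, str) else tuple(subset)
    sel = np.isin(ep.categories, subset)
    if not sel.any():
        raise ValueError(f"no trials in category subset {subset}")
    return sel


def compute_erp(ep: EpochSet, subset=None) -> ERPWaveform:
    """Average kept trials of ``subset`` categories (all if None).

    Per-trial baseline over [-1.0, 0) is subtracted before averaging and the
    result is multiplied by -1 (display convention).
    """
    sel = _select_trials(ep, subset)
    corrected = _baseline_corrected(ep)
    mask = ep.kept_mask & sel[:, None]
    n = mask.sum(axis=0)
    if (n == 0).any():
        bad = [ep.channels[i].name for i in np.nonzero(n == 0)[0]]
        raise ValueError(f"no kept trials on channels {bad} for subset {subset}")
    summed = np.einsum("ict,ic->ct", corrected, mask.astype(float))
    return ERPWaveform(-summed / n[:, None], n, ep.t.copy(), list(ep.channels))


def trial_peak_amplitudes(ep: EpochSet, windows=PEAK_WINDOWS) -> pd.DataFrame:
    """One row per kept trial x channel x peak window.

    ``amplitude_uv`` is the mean of the sign-flipped, baseline-corrected
    signal over the 80-ms window; rows carry full metadata for the
    mixed-effects models.
    """
    for w in windows:
        lo, hi = w.bounds_s
        if lo < ep.t[0] or hi > ep.t[-1] + 1.0 / ep.fs:
            raise ValueError(f"window {w.name} outside epoch span")
    corrected = -_baseline_corrected(ep)  # display sign
    rows = []
    for w in windows:
        m = ep.time_mask(*w.bounds_s)
        vals = corrected[:, :, m].mean(axis=2)  # trials x channels
        for ci, ch in enumerate(ep.channels):
            kept = np.nonzero(ep.kept_mask[:, ci])[0]
            for ti in kept:
                rows.append((ch.patient, ch.group, ch.hemisphere, ch.region,
                             ch.name, int(ti), ep.categories[ti], w.name,
                             vals[ti, ci]))
    return pd.DataFrame(rows, columns=["patient", "group", "hemisphere",
                                       "region", "channel", "trial",
                                       "category", "peak", "amplitude_uv"])
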