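"""Inter-regional phase-amplitude coupling and cross-frequency phase-slope
directionality.

PAC uses the mean-vector-length modulation index on a 3-20 Hz phase grid
(1-Hz steps) by a 45-200 Hz amplitude grid (5-Hz steps): phases and
amplitudes come from complex Morlet wavelets, restricted to the 0-750 ms
post-stimulus window and concatenated over kept trials.  Significance is a
surrogate z-score: each surrogate circularly time-shifts the concatenated
amplitude series against the phase series by a random offset of at least one
second, preserving both autocorrelations.

The phase-slope index (PSI) between a slow narrowband signal x and a gamma
envelope y is the imaginary part of sum_f conj(C(f)) C(f + df) over a band
around the phase frequency, where C is the complex coherency estimated from
750-ms Hann-tapered trial segments and df is one Rayleigh bin.  Positive PSI
means x temporally leads (modulates) y; the estimator is exactly
antisymmetric under exchanging x and y.  PSI z-scores come from surrogates
that permute the trial pairing between the two signals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_preprocess import EpochSet
from .timefreq import morlet_complex

__all__ = ["PHASE_FREQS", "AMP_FREQS", "PAC_WINDOW", "CouplingMap",
           "PSIResult", "extract_phase_amp", "pac_comodulogram",
           "phase_slope_index", "psi_map", "restrict_psi_to_pac",
           "choose_channel", "pac_between", "psi_between"]

PHASE_FREQS = np.arange(3.0, 21.0, 1.0)     # 18 frequencies
AMP_FREQS = np.arange(45.0, 201.0, 5.0)     # 32 frequencies
PAC_WINDOW = (0.0, 0.750)                   # s post-stimulus, half-open
PHASE_CYCLES = 4.0
AMP_CYCLES = 6.0
Z_THRESHOLD = 2.0


@dataclass
class CouplingMap:
    """Comodulogram: raw modulation index and surrogate z, amplitude
    frequencies x phase frequencies."""

    mi: np.ndarray
    z: np.ndarray
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    direction: str = ""       # "<phase_region>-phase -> <amp_region>-amp"
    condition: str = ""
    window: tuple = PAC_WINDOW
    n_surrogates: int = 0

    @property
    def significant(self) -> np.ndarray:
        return self.z >= Z_THRESHOLD


@dataclass
class PSIResult:
    """Signed directionality map on the same grids as the comodulogram.

    Positive values: the slow-phase site leads/modulates the gamma-amplitude
    site; negative: the reverse."""

    psi: np.ndarray
    z: np.ndarray
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    direction: str = ""
    condition: str = ""
    segment_s: float = 0.750
    n_surrogates: int = 0

    @property
    def significant(self) -> np.ndarray:
        return np.abs(self.z) >= Z_THRESHOLD


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_phase_amp(ep: EpochSet, channel: str, phase_freqs=PHASE_FREQS,
                      amp_freqs=AMP_FREQS, window=PAC_WINDOW,
                      trial_sel=None):
    """Morlet phase and amplitude series for one channel.

    Returns (phase: trials x n_phase_freqs x T, amp: trials x n_amp_freqs x T)
    restricted to the post-stimulus ``window``; wavelets are run on the full
    epoch so the window itself is free of edge effects.
    """
    phase_freqs = np.asarray(phase_freqs, dtype=float)
    amp_freqs = np.asarray(amp_freqs, dtype=float)
    if phase_freqs.min() < 3.0 or phase_freqs.max() > 20.0:
        raise ValueError("phase frequencies must lie in [3, 20] Hz")
    if amp_freqs.min() < 45.0 or amp_freqs.max() > 200.0:
        raise ValueError("amplitude frequencies must lie in [45, 200] Hz")
    ci = ep.ch_names.index(channel)
    data = ep.data[:, ci, :]
    if trial_sel is not None:
        data = data[trial_sel]
    wmask = ep.time_mask(*window)
    coef_p, _ = morlet_complex(data, ep.fs, phase_freqs,
                               n_cycles=np.full(phase_freqs.size, PHASE_CYCLES))
    coef_a, _ = morlet_complex(data, ep.fs, amp_freqs,
                               n_cycles=np.full(amp_freqs.size, AMP_CYCLES))
    phase = np.angle(np.moveaxis(coef_p, 0, 1))[:, :, wmask]
    amp = np.abs(np.moveaxis(coef_a, 0, 1))[:, :, wmask]
    return phase, amp


# ---------------------------------------------------------------------------
# PAC
# ---------------------------------------------------------------------------

def pac_comodulogram(phase: np.ndarray, amp: np.ndarray, fs: float,
                     n_surrogates: int = 200, rng=None, seed=None,
                     min_shift_s: float = 1.0, phase_freqs=PHASE_FREQS,
                     amp_freqs=AMP_FREQS, **map_kw) -> CouplingMap:
    """Mean-vector-length comodulogram with circular-shift surrogate z-scores.

    ``phase``: trials x n_phase_freqs x T (radians); ``amp``: trials x
    n_amp_freqs x T.  Trials are concatenated after windowing; every
    surrogate applies one global circular shift (>= ``min_shift_s``) of the
    concatenated amplitude series relative to the phase series.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_tr, n_p, n_t = phase.shape
    if amp.shape[0] != n_tr or amp.shape[2] != n_t:
        raise ValueError("phase and amplitude series must share trials and time")
    if n_tr < 10:
        warnings.warn("fewer than 10 usable trials; surrogate statistics "
                      "will be unstable")
    L = n_tr * n_t
    E = np.exp(1j * np.transpose(phase, (1, 0, 2)).reshape(n_p, L))
    A = np.transpose(amp, (1, 0, 2)).reshape(amp.shape[1], L)

    mi = np.abs(A @ E.T) / L                       # n_amp x n_phase

    min_shift = max(int(round(min_shift_s * fs)), n_t)
    if L <= 2 * min_shift:
        warnings.warn("concatenated series too short for the requested "
                      "minimum surrogate shift; using unrestricted offsets")
        offsets = rng.integers(1, L, size=n_surrogates)
    else:
        offsets = rng.integers(min_shift, L - min_shift, size=n_surrogates)

    # C_a,p(s) = (1/L) sum_t A_a(t+s) E_p(t), all s at once via FFT
    FA = np.fft.fft(A, axis=1)
    mi_surr = np.empty((A.shape[0], n_p, n_surrogates))
    for p in range(n_p):
        fp = np.fft.fft(np.conj(E[p]))
        r = np.fft.ifft(FA * np.conj(fp)[None, :], axis=1) / L
        mi_surr[:, p, :] = np.abs(r[:, offsets])

    mu = mi_surr.mean(axis=2)
    sd = mi_surr.std(axis=2, ddof=1)
    z = (mi - mu) / np.where(sd > 0, sd, np.inf)
    return CouplingMap(mi=mi, z=z,
                       phase_freqs=np.asarray(phase_freqs, float).copy(),
                       amp_freqs=np.asarray(amp_freqs, float).copy(),
                       n_surrogates=n_surrogates, **map_kw)


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def _tapered_rfft(segs: np.ndarray) -> np.ndarray:
    """Demean + Hann-taper each trial segment, return rfft (trials x F)."""
    segs = segs - segs.mean(axis=-1, keepdims=True)
    return np.fft.rfft(segs * np.hanning(segs.shape[-1])[None, :], axis=-1)


def _band_bins(freqs: np.ndarray, f_center: float, half_band: float):
    idx = np.nonzero((freqs >= f_center - half_band)
                     & (freqs <= f_center + half_band))[0]
    idx = idx[idx + 1 < freqs.size]
    if idx.size == 0:
        raise ValueError("empty PSI band; segment too short for this frequency")
    return idx

def phase_slope_index(x: np.ndarray, y: np.ndarray, fs: float,
                      f_center: float, half_band: float = 2.0) -> float:
    """Cross-frequency PSI between trials x T series ``x`` (slow signal) and
    ``y`` (envelope); positive = x leads y.  Exactly antisymmetric in (x, y)."""
    if x.shape != y.shape:
        raise ValueError("x and y must share shape (trials x time)")
    if x.shape[0] < 2:
        raise ValueError("need >= 2 trial segments for coherency estimation")
    X, Y = _tapered_rfft(np.asarray(x, float)), _tapered_rfft(np.asarray(y, float))
    freqs = np.fft.rfftfreq(x.shape[1], 1.0 / fs)
    sxy = (X * np.conj(Y)).mean(axis=0)
    sxx = (np.abs(X) ** 2).mean(axis=0)
    syy = (np.abs(Y) ** 2).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = sxy / np.sqrt(sxx * syy)
    c = np.nan_to_num(c)
    idx = _band_bins(freqs, f_center, half_band)
    return float(np.imag(np.sum(np.conj(c[idx]) * c[idx + 1])))


def psi_map(x: np.ndarray, y: np.ndarray, fs: float, phase_freqs=PHASE_FREQS,
            amp_freqs=AMP_FREQS, half_band: float = 2.0,
            n_surrogates: int = 200, rng=None, seed=None,
            **map_kw) -> PSIResult:
    """PSI over the comodulogram grids with trial-permutation surrogate z.

    ``x``: trials x n_phase_freqs x T narrowband slow signals (one per phase
    frequency); ``y``: trials x n_amp_freqs x T gamma envelopes.  The same
    surrogate trial permutations are reused across all grid pairs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    phase_freqs = np.asarray(phase_freqs, dtype=float)
    amp_freqs = np.asarray(amp_freqs, dtype=float)
    n_tr, n_t = x.shape[0], x.shape[2]
    freqs = np.fft.rfftfreq(n_t, 1.0 / fs)
    X = [_tapered_rfft(x[:, p, :]) for p in range(phase_freqs.size)]
    Y = [_tapered_rfft(y[:, a, :]) for a in range(amp_freqs.size)]
    perms = np.stack([rng.permutation(n_tr) for _ in range(n_surrogates)])

    psi = np.empty((amp_freqs.size, phase_freqs.size))
    z = np.empty_like(psi)
    for p, fp in enumerate(phase_freqs):
        idx = _band_bins(freqs, fp, half_band)
        sel = np.unique(np.concatenate([idx, idx + 1]))
        pos = np.searchsorted(sel, idx)
        Xb = X[p][:, sel]
        sxx = (np.abs(Xb) ** 2).mean(axis=0)
        for a in range(amp_freqs.size):
            Yb = Y[a][:, sel]
            syy = (np.abs(Yb) ** 2).mean(axis=0)
            norm = np.sqrt(sxx * syy)
            norm = np.where(norm > 0, norm, np.inf)
            c = (Xb * np.conj(Yb)).mean(axis=0) / norm
            psi[a, p] = np.imag(np.sum(np.conj(c[pos]) * c[pos + 1]))
            cs = (Xb[perms] * np.conj(Yb)[None]).mean(axis=1) / norm[None]
            psi_s = np.imag(np.sum(np.conj(cs[:, pos]) * cs[:, pos + 1],
                                   axis=1))
            sd = psi_s.std(ddof=1)
            z[a, p] = (psi[a, p] - psi_s.mean()) / (sd if sd > 0 else np.inf)
    return PSIResult(psi=psi, z=z, phase_freqs=phase_freqs.copy(),
                     amp_freqs=amp_freqs.copy(), segment_s=n_t / fs,
                     n_surrogates=n_surrogates, **map_kw)


def restrict_psi_to_pac(psi: PSIResult, pac: CouplingMap) -> PSIResult:
    """Mask PSI outside the PAC-significant (z >= 2) grid pairs with NaN."""
    if psi.psi.shape != pac.mi.shape or \
            not (np.allclose(psi.phase_freqs, pac.phase_freqs)
                 and np.allclose(psi.amp_freqs, pac.amp_freqs)):
        raise ValueError("PSI and PAC grids do not match")
    keep = pac.significant
    return PSIResult(psi=np.where(keep, psi.psi, np.nan),
                     z=np.where(keep, psi.z, np.nan),
                     phase_freqs=psi.phase_freqs.copy(),
                     amp_freqs=psi.amp_freqs.copy(), direction=psi.direction,
                     condition=psi.condition, segment_s=psi.segment_s,
                     n_surrogates=psi.n_surrogates)


# ---------------------------------------------------------------------------
# pipeline-level helpers
# ---------------------------------------------------------------------------

def choose_channel(ep: EpochSet, region: str) -> str:
    """Pick the region's channel with the fewest rejected epochs (ties broken
    by channel order)."""
    best, best_rejected = None, None
    for ci, ch in enumerate(ep.channels):
        if ch.region != region:
            continue
        rejected = int((~ep.kept_mask[:, ci]).sum())
        if best is None or rejected < best_rejected:
            best, best_rejected = ch.name, rejected
    if best is None:
        raise ValueError(f"no channel in region {region!r}")
    return best


def _common_trials(ep: EpochSet, ch_a: str, ch_b: str, categories=None):
    ia, ib = ep.ch_names.index(ch_a), ep.ch_names.index(ch_b)
    sel = ep.kept_mask[:, ia] & ep.kept_mask[:, ib]
    if categories is not None:
        cats = (categories,) if isinstance(categories, str) else tuple(categories)
        sel &= np.isin(ep.categories, cats)
    return sel


def pac_between(ep: EpochSet, phase_channel: str, amp_channel: str,
                categories=None, condition: str = "", n_surrogates: int = 200,
                rng=None, seed=None, phase_freqs=PHASE_FREQS,
                amp_freqs=AMP_FREQS) -> CouplingMap:
    """Comodulogram between ``phase_channel``'s slow phase and
    ``amp_channel``'s gamma amplitude on their common kept trials."""
    sel = _common_trials(ep, phase_channel, amp_channel, categories)
    phase, _ = extract_phase_amp(ep, phase_channel, phase_freqs, amp_freqs,
                                 trial_sel=sel)
    _, amp = extract_phase_amp(ep, amp_channel, phase_freqs, amp_freqs,
                               trial_sel=sel)
    pr = ep.channels[ep.ch_names.index(phase_channel)].region
    ar = ep.channels[ep.ch_names.index(amp_channel)].region
    return pac_comodulogram(phase, amp, ep.fs, n_surrogates=n_surrogates,
                            rng=rng, seed=seed, phase_freqs=phase_freqs,
                            amp_freqs=amp_freqs, condition=condition,
                            direction=f"{pr}-phase -> {ar}-amp")


def psi_between(ep: EpochSet, phase_channel: str, amp_channel: str,
                categories=None, condition: str = "", n_surrogates: int = 200,
                rng=None, seed=None, phase_freqs=PHASE_FREQS,
                amp_freqs=AMP_FREQS) -> PSIResult:
    """PSI between ``phase_channel``'s narrowband slow signal and
    ``amp_channel``'s gamma envelope on their common kept trials."""
    sel = _common_trials(ep, phase_channel, amp_channel, categories)
    ci = ep.ch_names.index(phase_channel)
    wmask = ep.time_mask(*PAC_WINDOW)
    coef_p, _ = morlet_complex(ep.data[sel, ci, :], ep.fs,
                               np.asarray(phase_freqs, float),
                               n_cycles=np.full(len(phase_freqs), PHASE_CYCLES))
    x = np.moveaxis(coef_p.real, 0, 1)[:, :, wmask]
    _, amp = extract_phase_amp(ep, amp_channel, phase_freqs, amp_freqs,
                               trial_sel=sel)
    pr = ep.channels[ci].region
    ar = ep.channels[ep.ch_names.index(amp_channel)].region
    return psi_map(x, amp, ep.fs, phase_freqs=phase_freqs,
                   amp_freqs=amp_freqs, n_surrogates=n_surrogates, rng=rng,
                   seed=seed, condition=condition,
                   direction=f"{pr}-phase -> {ar}-amp")
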