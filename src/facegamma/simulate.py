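"""Synthetic two-group intracranial-EEG study generator.

Emulates a passive face-viewing paradigm: six stimulus categories (five face
categories plus mosaics) of 50 pictures each, 1500-ms stimuli preceded by a
300-ms fixation cross, interstimulus intervals drawn uniformly from
2800-3000 ms.  Each synthetic patient carries depth contacts in up to four
temporal-lobe regions (amygdala, hippocampus, fusiform and parahippocampal
gyrus) plus a scalp Fz reference channel.  Patients belong to one of two
groups, "O" (no mesial temporal seizure onset zone) or "M" (mesial temporal
SOZ), and the configurable effects let group O and M differ exactly where the
analysis stages are supposed to detect it.

Signal model per channel:

* 1/f^alpha background noise (spectrum flattened below 1 Hz) at a configurable
  microvolt scale;
* phase-locked evoked deflections: Gaussian-windowed monophasic bumps at the
  nominal 110/240/360-ms latencies, identical across trials (they survive
  averaging);
* induced gamma bursts: band-limited noise carriers with a Hann envelope and
  independent phase per trial (they vanish from the trial average but raise
  single-trial power by a configurable decibel amount);
* optional cross-regional coupling: during post-stimulus windows the
  gamma-band envelope of one region is multiplied by
  (1 + depth * cos(phase of another region's slow rhythm, lagged)).

Contacts within a region share the evoked/induced effect up to a per-contact
gain gradient, so bipolar derivations (adjacent-contact differences) retain a
scaled copy of each effect instead of cancelling it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .io_preprocess import ChannelInfo, Recording

__all__ = [
    "CATEGORIES",
    "FACE_CATEGORIES",
    "REGIONS",
    "REGION_CODE",
    "ErpComponent",
    "GammaBurst",
    "CouplingSpec",
    "SimConfig",
    "schedule_events",
    "synthesize_recording",
    "inject_cross_regional_coupling",
    "generate_study",
]

CATEGORIES = ("caucasian", "dark_skinned", "famous", "veiled", "masks", "mosaic")
FACE_CATEGORIES = CATEGORIES[:5]
REGIONS = ("amygdala", "hippocampus", "fusiform", "parahippocampal")
REGION_CODE = {"amygdala": "AM", "hippocampus": "HI",
               "fusiform": "FU", "parahippocampal": "PH"}


@dataclass(frozen=True)
class ErpComponent:
    """A Gaussian-windowed evoked deflection added identically to every
    matching trial.  ``amplitude_uv`` is the raw signed peak (negative for the
    N-components); ``width_ms`` is the FWHM of the Gaussian envelope."""

    center_ms: float
    amplitude_uv: float
    width_ms: float = 60.0
    regions: tuple = REGIONS
    groups: tuple = ("O", "M")
    categories: tuple = FACE_CATEGORIES

    def matches(self, region, group, category):
        return (region in self.regions and group in self.groups
                and category in self.categories)


@dataclass(frozen=True)
class GammaBurst:
    """An induced gamma power increase: band-limited noise with a Hann
    envelope over ``window_ms`` post-onset and independent phase per trial.

    ``db_increase`` is the target mean decibel elevation over the burst's own
    band x window relative to the pre-stimulus baseline; the carrier spectrum
    follows the background 1/f shape inside the band so the elevation is flat
    across frequency."""

    low_hz: float
    high_hz: float
    db_increase: float
    window_ms: tuple = (100.0, 600.0)
    regions: tuple = ("amygdala", "fusiform")
    groups: tuple = ("O", "M")
    categories: tuple = FACE_CATEGORIES

    def matches(self, region, group, category):
        return (region in self.regions and group in self.groups
                and category in self.categories)


@dataclass(frozen=True)
class CouplingSpec:
    """Lagged slow-phase -> gamma-amplitude coupling between two regions."""

    phase_region: str
    amp_region: str
    phase_freq_hz: float = 6.0
    amp_band_hz: tuple = (60.0, 90.0)
    modulation_depth: float = 0.8
    lag_ms: float = 15.0
    categories: tuple = FACE_CATEGORIES
    window_ms: tuple = (0.0, 750.0)

    def __post_init__(self):
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if not 3.0 <= self.phase_freq_hz <= 20.0:
            raise ValueError("phase_freq_hz must lie in [3, 20] Hz")
        if not (45.0 <= self.amp_band_hz[0] < self.amp_band_hz[1] <= 200.0):
            raise ValueError("amp_band_hz must be a subrange of [45, 200] Hz")
        if abs(self.lag_ms) >= self.window_ms[1] - self.window_ms[0]:
            raise ValueError("lag exceeds the coupling window")


def _default_erp_components():
    # Effect directions mirror the study's findings: faces > mosaics at
    # N240/N360 in amygdala and fusiform (group O stronger in FU), a famous-
    # face N360 advantage in the parahippocampal gyrus, flat hippocampus.
    return (
        ErpComponent(110, -6.0, regions=("fusiform",)),
        ErpComponent(110, -3.0, regions=("fusiform",), categories=("mosaic",)),
        ErpComponent(240, -10.0, regions=("amygdala", "fusiform")),
        ErpComponent(240, -3.0, regions=("amygdala", "fusiform"),
                     categories=("mosaic",)),
        ErpComponent(240, -5.0, regions=("fusiform",), groups=("O",)),
        ErpComponent(360, -8.0, regions=("amygdala",), groups=("O",)),
        ErpComponent(360, -6.0, regions=("fusiform", "parahippocampal")),
        ErpComponent(360, -2.0, regions=("fusiform", "parahippocampal"),
                     categories=("mosaic",)),
        ErpComponent(360, -6.0, regions=("parahippocampal",),
                     categories=("famous",)),
    )


def _default_gamma_effects():
    return (
        GammaBurst(45, 95, 3.0, regions=("amygdala", "fusiform"), groups=("O",)),
        GammaBurst(45, 95, 2.0, regions=("parahippocampal",),
                   categories=CATEGORIES),
        GammaBurst(60, 120, 1.5, window_ms=(350.0, 900.0),
                   regions=("hippocampus",), categories=("famous",)),
    )


def _default_coupling_specs():
    return (
        CouplingSpec("fusiform", "amygdala", 6.0, (60.0, 90.0), 0.6, 15.0),
        CouplingSpec("parahippocampal", "hippocampus", 10.0, (80.0, 120.0),
                     0.6, 15.0),
    )


@dataclass
class SimConfig:
    """Free parameters of the synthetic study.

    Paradigm timings default to the study conditions (6 x 50 stimuli, ISI
    2800-3000 ms, 300-ms fixation, 1500-ms stimulus).  Effect amplitudes are
    illustrative: the source study reports no per-trial amplitude
    distributions, so the defaults are chosen to be realistic for mesial
    temporal LFP and to point in the reported directions.
    """

    n_patients_per_group: int = 3
    regions: tuple = REGIONS
    n_contacts: int = 2
    contact_gains: tuple = (1.0, 0.45)
    fs: int = 1024
    n_per_category: int = 50
    isi_range_ms: tuple = (2800.0, 3000.0)
    fixation_ms: float = 300.0
    stim_ms: float = 1500.0
    one_over_f_exponent: float = 1.5
    noise_scale_uv: float = 20.0
    erp_components: tuple = field(default_factory=_default_erp_components)
    gamma_effects: tuple = field(default_factory=_default_gamma_effects)
    coupling_specs: tuple = field(default_factory=_default_coupling_specs)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_category < 1 or self.n_patients_per_group < 1:
            raise ValueError("counts must be positive")
        if self.isi_range_ms[0] > self.isi_range_ms[1]:
            raise ValueError("isi_range lower bound exceeds upper bound")
        if int(self.fs) not in (1024, 2048):
            raise ValueError("fs must be 1024 or 2048")
        if len(self.contact_gains) != self.n_contacts:
            raise ValueError("need one gain per contact")
        for c in self.erp_components:
            if not np.isfinite(c.amplitude_uv):
                raise ValueError("ERP amplitudes must be finite")
            for r in c.regions:
                if r not in REGIONS:
                    raise ValueError(f"unknown region {r!r}")
        for g in self.gamma_effects:
            for r in g.regions:
                if r not in REGIONS:
                    raise ValueError(f"unknown region {r!r}")


# ---------------------------------------------------------------------------
# event schedule
# ---------------------------------------------------------------------------

def schedule_events(config: SimConfig, rng=None) -> pd.DataFrame:
    """Randomized stimulus schedule: one onset per (category, repetition).

    Consecutive onsets are separated by stimulus duration + ISI + fixation,
    with the ISI drawn uniformly from ``isi_range_ms``.  Returns a DataFrame
    with columns onset_s, category, duration_s; ``attrs['recording_s']``
    holds the total duration including 2 s of padding at both ends.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = np.repeat(CATEGORIES, config.n_per_category)
    labels = labels[rng.permutation(labels.size)]
    isi_s = rng.uniform(*config.isi_range_ms, size=labels.size - 1) / 1000.0
    gaps = (config.stim_ms + config.fixation_ms) / 1000.0 + isi_s
    onsets = 2.0 + np.concatenate([[0.0], np.cumsum(gaps)])
    df = pd.DataFrame({
        "onset_s": onsets,
        "category": labels,
        "duration_s": config.stim_ms / 1000.0,
    })
    df.attrs["recording_s"] = float(
        np.ceil(onsets[-1] + config.stim_ms / 1000.0 + 2.0))
    return df


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _spectral_shape(freqs, alpha, shelf_hz=1.0):
    """Amplitude shaping g(f) ~ 1/max(f, shelf)^(alpha/2), DC removed."""
    g = np.maximum(freqs, shelf_hz) ** (-alpha / 2.0)
    g[0] = 0.0
    return g


def _pink_noise(n, fs, alpha, scale, rng):
    """Spectrally shaped Gaussian noise normalized to SD ``scale``.

    Returns (signal, band_power_fraction) where the callable fraction(lo, hi)
    gives the expected share of total variance inside [lo, hi] Hz.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    g = _spectral_shape(freqs, alpha)
    spec = g * (rng.standard_normal(g.size) + 1j * rng.standard_normal(g.size))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd > 0:
        x *= scale / sd

    g2 = g ** 2
    total = g2.sum()

    def band_fraction(lo, hi):
        m = (freqs >= lo) & (freqs <= hi)
        return g2[m].sum() / total

    return x, band_fraction


def _band_noise(n, fs, lo, hi, alpha, rng):
    """Unit-variance noise confined to [lo, hi] Hz whose in-band spectrum
    follows the 1/f^alpha background shape."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    g = _spectral_shape(freqs, alpha)
    g[(freqs < lo) | (freqs > hi)] = 0.0
    spec = g * (rng.standard_normal(g.size) + 1j * rng.standard_normal(g.size))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _gaussian_bump(t, center_s, fwhm_s):
    sigma = fwhm_s / 2.3548200450309493
    return np.exp(-0.5 * ((t - center_s) / sigma) ** 2)


def synthesize_recording(config: SimConfig, events: pd.DataFrame, patient: str,
                         group: str, hemisphere: str = "L",
                         rng=None) -> Recording:
    """Render one patient's continuous recording for a given event schedule."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for r in config.regions:
        if r not in REGIONS:
            raise ValueError(f"unknown region {r!r}")
    fs = int(config.fs)
    duration = events.attrs.get(
        "recording_s",
        float(np.ceil(events["onset_s"].iloc[-1] + config.stim_ms / 1000.0 + 2.0)))
    n = int(round(duration * fs))
    tgrid = np.arange(n) / fs

    onsets = events["onset_s"].to_numpy()
    cats = events["category"].to_numpy()

    names, infos, rows = [], [], []
    region_signals = {}
    for region in config.regions:
        code = REGION_CODE[region]
        contacts = np.empty((config.n_contacts, n))
        band_frac = None
        for k in range(config.n_contacts):
            bg, frac = _pink_noise(n, fs, config.one_over_f_exponent,
                                   config.noise_scale_uv, rng)
            contacts[k] = bg
            band_frac = frac

        # shared per-region effect trace, scaled per contact by its gain
        effect = np.zeros(n)
        for comp in config.erp_components:
            if region not in comp.regions or group not in comp.groups:
                continue
            n_half = int(round(2 * comp.width_ms / 1000.0 * fs))
            center = comp.center_ms / 1000.0
            bump_t = center + np.arange(-n_half, n_half + 1) / fs
            bump = comp.amplitude_uv * _gaussian_bump(
                bump_t, center, comp.width_ms / 1000.0)
            for onset, cat in zip(onsets, cats):
                if cat not in comp.categories:
                    continue
                i0 = int(round(onset * fs)) + int(round(center * fs)) - n_half
                seg = slice(max(i0, 0), min(i0 + bump.size, n))
                effect[seg] += bump[seg.start - i0:seg.stop - i0]

        for burst in config.gamma_effects:
            if region not in burst.regions or group not in burst.groups:
                continue
            w0, w1 = burst.window_ms[0] / 1000.0, burst.window_ms[1] / 1000.0
            wlen = int(round((w1 - w0) * fs))
            env = np.hanning(wlen)
            # mean in-band dB elevation over the window equals db_increase
            pb = config.noise_scale_uv ** 2 * band_frac(burst.low_hz, burst.high_hz)
            amp = np.sqrt(pb * (10 ** (burst.db_increase / 10.0) - 1.0)
                          / np.mean(env ** 2))
            for onset, cat in zip(onsets, cats):
                if cat not in burst.categories:
                    continue
                carrier = _band_noise(wlen, fs, burst.low_hz, burst.high_hz,
                                      config.one_over_f_exponent, rng)
                i0 = int(round((onset + w0) * fs))
                seg = slice(i0, min(i0 + wlen, n))
                effect[seg] += (amp * env * carrier)[:seg.stop - seg.start]

        for k, gain in enumerate(config.contact_gains):
            contacts[k] += gain * effect

        region_signals[region] = contacts
        for k in range(config.n_contacts):
            names.append(f"{code}{k + 1}_{hemisphere[0]}")
            infos.append(ChannelInfo(names[-1], region, hemisphere, patient, group))

    # cross-regional coupling, applied to full contact signals
    for spec in config.coupling_specs:
        if spec.phase_region not in region_signals or \
           spec.amp_region not in region_signals:
            continue
        phase_sig = region_signals[spec.phase_region][0]
        amp_contacts = region_signals[spec.amp_region]
        for k in range(config.n_contacts):
            amp_contacts[k] = inject_cross_regional_coupling(
                phase_sig, amp_contacts[k], fs, events, spec)

    for region in config.regions:
        for k in range(config.n_contacts):
            rows.append(region_signals[region][k])

    # scalp Fz reference channel: independent low-amplitude noise
    fz, _ = _pink_noise(n, fs, config.one_over_f_exponent,
                        config.noise_scale_uv / 4.0, rng)
    rows.append(fz)
    infos.append(ChannelInfo("Fz", "scalp-Fz", hemisphere, patient, group))

    return Recording(np.vstack(rows), float(fs), infos)


def _narrowband_phase(x, fs, f0, half_bw=1.5):
    """Instantaneous phase of x restricted to f0 +/- half_bw (zero-phase
    brick-wall in the frequency domain, then analytic signal)."""
    n = x.size
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.fft.rfft(x)
    spec[(freqs < f0 - half_bw) | (freqs > f0 + half_bw)] = 0.0
    nb = np.fft.irfft(spec, n=n)
    return np.angle(hilbert(nb))


def inject_cross_regional_coupling(phase_sig, amp_sig, fs, events,
                                   spec: CouplingSpec):
    """Return ``amp_sig`` with its gamma-band component multiplied by
    ``1 + depth*cos(phase of phase_sig at phase_freq, lagged by lag_ms)``
    during post-stimulus windows of the matching categories.

    Only ``amp_sig`` is modified; ``phase_sig`` is read-only.  With
    ``modulation_depth == 0`` the signal is returned bit-identical.
    """
    if spec.modulation_depth == 0.0:
        return np.asarray(amp_sig, dtype=float).copy()
    amp_sig = np.asarray(amp_sig, dtype=float)
    n = amp_sig.size
    fs = float(fs)

    phi = _narrowband_phase(np.asarray(phase_sig, dtype=float), fs,
                            spec.phase_freq_hz)
    lag = int(round(spec.lag_ms / 1000.0 * fs))
    phi_lagged = np.roll(phi, lag)  # phi(t - lag)

    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec_fft = np.fft.rfft(amp_sig)
    band = (freqs >= spec.amp_band_hz[0]) & (freqs <= spec.amp_band_hz[1])
    in_band = np.fft.irfft(np.where(band, spec_fft, 0.0), n=n)
    rest = amp_sig - in_band

    # smooth 10-ms cosine-ramped gate over each matching window
    gate = np.zeros(n)
    ramp = int(round(0.010 * fs))
    w0, w1 = spec.window_ms[0] / 1000.0, spec.window_ms[1] / 1000.0
    for onset, cat in zip(events["onset_s"], events["category"]):
        if cat not in spec.categories:
            continue
        a, b = int(round((onset + w0) * fs)), int(round((onset + w1) * fs))
        a, b = max(a, 0), min(b, n)
        if b <= a:
            continue
        win = np.ones(b - a)
        r = min(ramp, (b - a) // 2)
        if r > 0:
            edge = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
            win[:r], win[-r:] = edge, edge[::-1]
        gate[a:b] = np.maximum(gate[a:b], win)

    mod = 1.0 + gate * spec.modulation_depth * np.cos(phi_lagged)
    return rest + in_band * mod


# ---------------------------------------------------------------------------
# study-level driver
# ---------------------------------------------------------------------------

def generate_study(config: SimConfig, out_dir=None):
    """Generate the full two-group study: one recording + event schedule per
    patient, deterministic under ``config.seed``.

    If ``out_dir`` is given, writes per patient ``<id>.edf`` and
    ``<id>_events.tsv`` plus a single ``channels.tsv``; always returns a dict
    ``{patient_id: (Recording, events DataFrame)}``.
    """
    root = np.random.SeedSequence(config.seed)
    patients = {}
    meta_rows = []
    pid = 0
    for group in ("O", "M"):
        for j in range(config.n_patients_per_group):
            pid += 1
            name = f"P{pid:02d}"
            hemi = "L" if pid % 2 else "R"
            child = np.random.SeedSequence(entropy=root.entropy,
                                           spawn_key=(pid,))
            rng = np.random.default_rng(child)
            events = schedule_events(config, rng=rng)
            rec = synthesize_recording(config, events, name, group, hemi, rng=rng)
            patients[name] = (rec, events)
            for c in rec.channels:
                meta_rows.append({"channel": c.name, "region": c.region,
                                  "hemisphere": c.hemisphere, "patient": name,
                                  "group": group})
            if out_dir is not None:
                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                from ._edf import write_edf
                try:
                    write_edf(out / f"{name}.edf", rec.data, int(rec.fs),
                              rec.ch_names)
                    events.to_csv(out / f"{name}_events.tsv", sep="\t",
                                  index=False)
                except OSError as err:
                    raise OSError(
                        f"failed writing outputs for {name} under {out}: {err}"
                    ) from err
    if out_dir is not None:
        pd.DataFrame(meta_rows).to_csv(Path(out_dir) / "channels.tsv",
                                       sep="\t", index=False)
    return patients
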