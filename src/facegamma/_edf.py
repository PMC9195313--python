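"""Minimal plain-EDF (16-bit) writer and an mne-backed reader.

The writer produces standard EDF: one 256-byte global header, one 256-byte
header per signal, then 1-second data records of little-endian int16 samples.
Physical units are microvolts throughout. Reading goes through mne's native
EDF reader and converts back to microvolts.
"""
from __future__ import annotations

import numpy as np

__all__ = ["write_edf", "read_edf"]

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long ({s!r} > {width} chars)")
    return s.ljust(width).encode("ascii")


def write_edf(path, data_uv: np.ndarray, fs: int, ch_names) -> None:
    """Write ``data_uv`` (channels x samples, microvolts) as plain EDF.

    The sampling rate must be an integer (record duration is fixed at 1 s);
    the recording is zero-padded to a whole number of seconds.
    """
    data_uv = np.asarray(data_uv, dtype=float)
    if data_uv.ndim != 2:
        raise ValueError("data must be channels x samples")
    fs = int(fs)
    n_ch, n_samp = data_uv.shape
    if len(ch_names) != n_ch:
        raise ValueError("channel name count does not match data")
    n_rec = int(np.ceil(n_samp / fs))
    if n_rec * fs != n_samp:
        pad = np.zeros((n_ch, n_rec * fs - n_samp))
        data_uv = np.hstack([data_uv, pad])

    # per-channel symmetric physical range; digital full scale
    pmax = np.maximum(np.max(np.abs(data_uv), axis=1) * 1.05, 1.0)
    pmin = -pmax

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field("01.01.20", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )

    def sig(fmt, width):
        return b"".join(_field(fmt(i), width) for i in range(n_ch))

    header += sig(lambda i: str(ch_names[i])[:16], 16)
    header += sig(lambda i: "", 80)
    header += sig(lambda i: "uV", 8)
    header += sig(lambda i: f"{pmin[i]:.6g}"[:8], 8)
    header += sig(lambda i: f"{pmax[i]:.6g}"[:8], 8)
    header += sig(lambda i: str(_DIG_MIN), 8)
    header += sig(lambda i: str(_DIG_MAX), 8)
    header += sig(lambda i: "", 80)
    header += sig(lambda i: str(fs), 8)
    header += sig(lambda i: "", 32)

    # physical -> digital, per channel
    gain = (_DIG_MAX - _DIG_MIN) / (2 * pmax)
    digital = np.round((data_uv - pmin[:, None]) * gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # records: for each second, all channels contiguously
        recs = digital.reshape(n_ch, n_rec, fs)
        for r in range(n_rec):
            fh.write(recs[:, r, :].tobytes())


def read_edf(path):
    """Read an EDF file; returns (data_uv: channels x samples, fs, ch_names)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne stores Volts
    return data_uv, float(raw.info["sfreq"]), list(raw.ch_names)
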