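"""Factories shared across test modules."""
from __future__ import annotations

import numpy as np

from facegamma.io_preprocess import ChannelInfo, EpochSet


def make_channels(n=1, region="amygdala", patient="P01", group="O", hemi="L"):
    code = {"amygdala": "AM", "hippocampus": "HI", "fusiform": "FU",
            "parahippocampal": "PH"}[region]
    return [ChannelInfo(f"{code}{i + 1}_{hemi}", region, hemi, patient, group)
            for i in range(n)]


def make_epochs(data, fs=1024.0, categories=None, reference="none",
                channels=None, tmin=-1.1):
    """EpochSet from a raw trials x channels x time array."""
    data = np.asarray(data, dtype=float)
    n_tr, n_ch, n_t = data.shape
    t = (np.arange(n_t) + int(round(tmin * fs))) / fs
    if categories is None:
        categories = np.array(["caucasian"] * n_tr)
    if channels is None:
        channels = make_channels(n_ch)
    return EpochSet(data, t, fs, reference, channels, np.asarray(categories))
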