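"""Induced gamma power: ERP-subtracted bipolar epochs, 40 log-spaced Morlet
frequencies (1-200 Hz), decibel baseline over the 1100-ms pre-stimulus span,
mean 45-150 Hz power in the per-region window (hippocampus 250-1000 ms,
others 0-750 ms)."""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, run_through

run_through("tfr")
rows = pd.read_csv(RESULTS / "gamma_trials.tsv", sep="\t")
rows["picture"] = rows["category"].where(rows["category"] == "mosaic", "face")
summary = (rows.groupby(["region", "group", "picture"])["gamma_db"]
           .mean().unstack("picture").round(3))
print(f"{len(rows)} trial rows -> {RESULTS/'gamma_trials.tsv'}")
print("mean windowed gamma power (dB) by region/group:")
print(summary.to_string())
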