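"""Trial-level ERP peak amplitudes (N110/N240/N360, 80-ms windows,
sign-flipped so negative deflections read positive) pooled over patients."""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, run_through

run_through("erp")
rows = pd.read_csv(RESULTS / "erp_trials.tsv", sep="\t")
rows["picture"] = rows["category"].where(rows["category"] == "mosaic", "face")
summary = (rows.groupby(["region", "group", "picture", "peak"])
           ["amplitude_uv"].mean().unstack("peak").round(2))
print(f"{len(rows)} trial rows -> {RESULTS/'erp_trials.tsv'}")
print("mean amplitude (µV, display sign) by region/group/picture:")
print(summary.to_string())
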