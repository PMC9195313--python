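"""Group comparison of face-minus-mosaic time-frequency maps: pooled
two-sample t per pixel, voxel threshold p = 0.05, 4-connected clusters,
max/min-sum permutation null (positive t = stronger face response in group
O, the group without a mesial temporal seizure onset zone)."""
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, run_through

run_through("cluster")
thr = json.loads((RESULTS / "cluster_thresholds.json").read_text())
clusters = pd.read_csv(RESULTS / "clusters.tsv", sep="\t")
for region, t in thr.items():
    n = int((clusters["region"] == region).sum()) if len(clusters) else 0
    print(f"{region}: {n} surviving cluster(s); cluster-sum thresholds "
          f"[{t['thr_lo']:.1f}, {t['thr_hi']:.1f}], voxel |t| >= "
          f"{t['voxel_threshold']:.2f}")
if len(clusters):
    print(clusters.round(2).to_string(index=False))
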