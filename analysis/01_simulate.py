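"""Generate the synthetic two-group iEEG study.

Six patients (3 without a mesial temporal seizure onset zone, group O; 3
with one, group M) passively view 6 x 12 stimuli; each patient gets an EDF
recording with amygdala / hippocampus / fusiform / parahippocampal depth
contacts plus scalp Fz, an events TSV and shared channel metadata.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, run_through

run_through("simulate")
manifest = json.loads((RESULTS / "manifest.json").read_text())
counts = manifest["stages"]["simulate"]["events_per_patient"]
print(f"wrote {len(counts)} patients under {RESULTS/'input'}")
for pid, n in counts.items():
    print(f"  {pid}: {n} stimulus events")
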