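"""Read the EDFs back, resample to 1024 Hz, re-reference (Fz-monopolar for
the ERP path, bipolar for the gamma path), epoch [-1.1, 1.5) s and reject
epochs whose SD exceeds 2.5 x the per-channel mean epoch SD."""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, run_through

run_through("preprocess")
pre = json.loads((RESULTS / "manifest.json").read_text())["stages"]["preprocess"]
for pid, c in pre.items():
    print(f"{pid}: {c['trials']} trials; rejected {c['erp_rejected']} "
          f"(ERP path) / {c['gamma_rejected']} (gamma path) channel-epochs")
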