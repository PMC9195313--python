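"""Mixed-effects group statistics: REML fits with a random patient
intercept; model 1 (group x face-vs-mosaic + hemisphere [+ peaks]) and
model 2 (face categories only), Holm-corrected terms, Tukey post-hoc where
the interaction is significant; per-contact responsiveness flags."""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, run_through

run_through("stats")
for f in sorted(RESULTS.glob("lme_*_model1_*.tsv")):
    if "posthoc" in f.name:
        continue
    terms = pd.read_csv(f, sep="\t")
    sig = terms[terms["p_holm"] < 0.05]
    print(f"{f.stem}: " + (", ".join(
        f"{r.term} (p_holm={r.p_holm:.3g})" for r in sig.itertuples())
        or "no significant terms"))
flags = pd.read_csv(RESULTS / "responsive_contacts.tsv", sep="\t")
print(f"responsive contacts: {flags['erp_responsive'].sum()}/{len(flags)} ERP,"
      f" {flags['gamma_responsive'].sum()}/{len(flags)} gamma")
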