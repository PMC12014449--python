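"""Generate the synthetic study bundle every downstream step consumes.

Writes a 4-food x 7-day x 3-replicate roasting concentration table, one
transwell assay per concentration replicate, and per-group intake surveys
(500 people per food) to results/study/, together with the ground-truth
manifest the recovery checks compare against.
"""

import sys
from pathlib import Path

from fluorisk.synthetic import paper_shaped_design, study_bundle

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240409
OUT = Path(__file__).resolve().parents[1] / "results" / "study"

manifest = study_bundle(SEED, OUT, paper_shaped_design())
n_assays = sum(len(v) for v in manifest["rba_targets"].values())
print(f"seed {SEED}: wrote study bundle to {OUT}")
print(f"  foods: {sorted(manifest['curves'])}")
print(f"  concentration records: 4 foods x 7 days x 3 replicates = 84")
print(f"  intake surveys: {len(manifest['intake_truth'])} group-food series "
      f"x {manifest['design']['survey_n']} people")
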