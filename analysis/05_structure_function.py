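"""Structure-function association battery and the final report.

Partial correlations (age and mask-size covariates, per-column 3-SD
exclusions, per-family Bonferroni thresholds) between structural scalars,
d' and mask power. Writes associations.tsv/.json, then renders report.md
summarizing all stages.
"""

import argparse
import json
from pathlib import Path

from wmosc import PipelineConfig
from wmosc.pipeline import stage_correlate, write_report

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/run"))
args = parser.parse_args()

cfg = PipelineConfig.from_yaml(args.out / "config.yaml")
stage_correlate(cfg, args.out)
with open(args.out / "associations.json") as fh:
    results = json.load(fh)
for r in results:
    flag = "*" if r["significant"] else " "
    print(
        f"{flag} {r['x_name']} ~ {r['y_name']} | {','.join(r['covariate_names'])}: "
        f"r = {r['r_partial']:.3f}, p = {r['p']:.4f} (threshold {r['alpha_corrected']:.4f})"
    )
try:
    write_report(args.out)
    print(f"report written to {args.out / 'report.md'}")
except Exception as e:  # manifest-free partial runs still get a report
    print(f"report: {e}")
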