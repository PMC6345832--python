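"""Score the change-detection task and test the load effect.

Reads trials.tsv from the run directory; writes behavior_summary.tsv
(per-subject d', hit/false-alarm rates, median RT per load) and
behavior_stats.json (repeated-measures ANOVAs with planned Bonferroni
contrasts at 0.05/3). Expect accuracy to fall and reaction time to rise
with memory load.
"""

import argparse
import json
from pathlib import Path

from wmosc import PipelineConfig
from wmosc.pipeline import stage_behavior

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/run"))
args = parser.parse_args()

cfg = PipelineConfig.from_yaml(args.out / "config.yaml")
stage_behavior(cfg, args.out)
with open(args.out / "behavior_stats.json") as fh:
    stats = json.load(fh)
for measure in ("dprime", "median_rt"):
    a = stats[measure]["anova"]
    print(f"{measure}: F({a['df1']}, {a['df2']}) = {a['F']:.2f}, p = {a['p']:.4g}")
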