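"""Cluster-based permutation test of the load contrast and extraction of
per-subject power within the group significance mask.

Tests the configured contrast (high vs low load by default) over the
1-3 s retention window with per-subject sign-flip permutations, the
minimum-neighbor-channel rule, and alpha = 0.025 per direction. Writes
clusters.json, the group mask, and mask_power.tsv.
"""

import argparse
import json
from pathlib import Path

from wmosc import PipelineConfig
from wmosc.pipeline import stage_clusterstat

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/run"))
args = parser.parse_args()

cfg = PipelineConfig.from_yaml(args.out / "config.yaml")
counts = stage_clusterstat(cfg, args.out)
with open(args.out / "clusters.json") as fh:
    doc = json.load(fh)
sig = [c for c in doc["clusters"] if c["significant"]]
if not sig:
    print("no significant clusters")
for c in sig:
    print(
        f"{c['sign']} cluster: mass {c['mass']:.1f}, p = {c['p_mc']:.4f}, "
        f"{c['freq_min']:.1f}-{c['freq_max']:.1f} Hz, "
        f"{c['time_min']:.2f}-{c['time_max']:.2f} s, {c['n_samples']} samples"
    )
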