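"""Generate the synthetic study: sensor layout, EEG epochs, trial table,
and structural subject table.

The default run uses the scaled-down geometry (12 subjects, 16 channels,
20 trials per load); pass --full for the study design proper (31
subjects, 60 channels, 60 trials per load — substantially slower).
Outputs land in results/run/.
"""

import argparse
from pathlib import Path

from wmosc import PipelineConfig
from wmosc.pipeline import stage_simulate

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/run"))
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--full", action="store_true", help="full 31x60x60 geometry")
args = parser.parse_args()

cfg = PipelineConfig.full_scale(seed=args.seed) if args.full else PipelineConfig(seed=args.seed)
args.out.mkdir(parents=True, exist_ok=True)
cfg.to_yaml(args.out / "config.yaml")
counts = stage_simulate(cfg, args.out)
print(
    f"simulated {counts['n_subjects']} subjects, {counts['n_trials']} trials; "
    f"epochs, trials.tsv, subjects.tsv and layout.json written to {args.out}"
)
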