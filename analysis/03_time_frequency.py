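"""Morlet time-frequency decomposition with relative baseline correction.

For every subject: single-trial wavelet power (4 cycles) on the 4-30 Hz
grid, averaged per load condition, then expressed as relative change from
the 150-50 ms pre-sample baseline. Writes per-subject tfr binaries under
results/run/tfr/. The retention-phase theta-alpha desynchronization should
deepen with load.
"""

import argparse
from pathlib import Path

from wmosc import PipelineConfig
from wmosc.pipeline import stage_tfr

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/run"))
args = parser.parse_args()

cfg = PipelineConfig.from_yaml(args.out / "config.yaml")
counts = stage_tfr(cfg, args.out)
print(f"wrote {counts['n_tfr_maps']} baseline-corrected condition maps to {args.out / 'tfr'}")
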