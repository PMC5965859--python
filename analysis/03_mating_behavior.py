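"""Mating-behavior analysis: contingency tests, mixed models, plasticity
regressions.

Reads data/courtship.csv (and the capacity tables from the cold-tolerance
step, if present, for the physiology-behavior regressions); writes the
contingency report, latency/duration model tables, per-line behavior
summaries and regressions under results/.
"""

import argparse
import json
from pathlib import Path

from coldsong.pipeline import PipelineConfig, run_mating_stage

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--data-dir", type=Path, default=Path("data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cfg = PipelineConfig(input_dir=args.data_dir, output_dir=args.out,
                     seed=args.seed)
paths = run_mating_stage(cfg)
report = json.loads(Path(paths["contingency"]).read_text())
chi2 = report["chi2"]
print(f"mating vs male treatment: chi2 = {chi2['statistic']:.2f} "
      f"(df {chi2['df']}, p = {chi2['p']:.2g}, "
      f"continuity={'on' if report['continuity_default'] else 'off'})")
for name, path in paths.items():
    print(f"  {name}: {path}")
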