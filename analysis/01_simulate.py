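"""Generate the synthetic study dataset.

Emulates the experimental design: 19 DGRP lines x 2 sexes x 2 cold
treatments x 4 replicate vials of 10 flies for survival; 4 male x female
acclimation pairings x 6 replicates per line for the 4-hour mating screen;
148 pulse-song recordings (WAV + metadata) over 5 lines x 2 male treatments
with recording temperatures near 25 degC.
"""

import argparse
from pathlib import Path

from coldsong.pipeline import PipelineConfig, run_simulate_stage

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--data-dir", type=Path, default=Path("data"))
parser.add_argument("--n-songs", type=int, default=148)
args = parser.parse_args()

cfg = PipelineConfig(input_dir=args.data_dir, seed=args.seed)
paths = run_simulate_stage(cfg, n_songs=args.n_songs)
print(f"wrote synthetic dataset (seed {args.seed}):")
for name, path in paths.items():
    print(f"  {name}: {path}")
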