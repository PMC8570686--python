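#!/usr/bin/env python
"""Generate the default synthetic study dataset.

Three groups — high-expression (clozapine suppresses the evoked
response), low-expression (extra population spikes, reduced
paired-pulse inhibition) and a reporter-only control — with EP sweep
grids, two broadband probe recordings, morphometry tables, ROI
intensities and expression scores. Raw data (including the flat-binary
broadband files) go under scratch/ by default; all later stages read
from there.
"""
import argparse
from pathlib import Path

from dgep.pipeline import default_study_config, simulate

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch/dataset")
    args = ap.parse_args()
    study = default_study_config(args.seed)
    simulate(study, args.out)
    n = sum(g.n_animals for g in study.groups)
    print(f"simulated {n} animals across {len(study.groups)} groups "
          f"(seed {args.seed}) -> {args.out}")
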