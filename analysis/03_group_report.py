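#!/usr/bin/env python
"""Build the group-level statistical report.

Paired vehicle-vs-clozapine contrasts on the normalized EP effects,
injected-vs-non-injected volume contrasts, and the signed-rank pre/post
contrast on unit rates, all with Holm step-down adjustment. Tables land
in results/report/.
"""
import argparse
from pathlib import Path

import pandas as pd

from dgep.pipeline import report

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="indir", type=Path,
                    default=ROOT / "results/analysis")
    ap.add_argument("--out", type=Path, default=ROOT / "results/report")
    ap.add_argument("--holm-family", default="per_metric",
                    choices=["per_metric", "global"])
    args = ap.parse_args()
    report(args.indir, args.out, args.holm_family)

    comp = pd.read_csv(args.out / "comparisons.csv")
    sig = comp[comp.p_adjusted < 0.05]
    print(f"{len(comp)} comparisons, {len(sig)} significant after "
          f"Holm adjustment ({args.holm_family} families):")
    for _, row in sig.iterrows():
        print(f"  {row.label}: stat={row.statistic:.2f} "
              f"p_adj={row.p_adjusted:.4f}")
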