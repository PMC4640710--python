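#!/usr/bin/env python
"""Render the lagged-vs-proximity comparison figures from the written tables.

White bars: lagged/predictive.  Grey bars: temporal proximity/causal.
Whiskers: 95% CIs.  The plotted numbers are re-written next to each figure
(fig_*_data.csv) so the rendering is auditable against the tables.
"""

import argparse
from pathlib import Path

import pandas as pd

from proxrisk.pipeline import ReportBundle, render_comparison_figures


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    auc, fits = {}, {}
    for d in ("lagged", "proximity"):
        if (args.results / f"auc_{d}.csv").exists():
            auc[d] = pd.read_csv(args.results / f"auc_{d}.csv")
        if (args.results / f"fits_{d}.csv").exists():
            fits[d] = pd.read_csv(args.results / f"fits_{d}.csv")
    bundle = ReportBundle(config=None, seed=None, summary={}, auc=auc, fits=fits,
                          correlations=pd.DataFrame(), screens={}, attenuation={})
    made = render_comparison_figures(bundle, args.results)
    for line in bundle.log:
        print(line)
    print("\n".join(made) if made else "nothing rendered (run stages 03/04 first)")


if __name__ == "__main__":
    main()
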