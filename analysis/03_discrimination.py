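#!/usr/bin/env python
"""Clustered AUC per item under each design; flag the lagged-vs-proximity gaps.

Writes one AUC table per design (subject-cluster jackknife CIs) and reports
which items discriminate significantly better under temporal proximity than
under the lagged design, judged by disjoint 95% CIs — in the calibrated
simulation these are the proximal items and the risk totals.
"""

import argparse
from pathlib import Path

from proxrisk.discrimination import auc_table
from proxrisk.panel_io import read_panel
from proxrisk.windows import build_design


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    panel = read_panel(args.results / "panel.csv")

    tables = {}
    for design in ("lagged", "proximity", "static"):
        tab = auc_table(build_design(panel, design))
        tab.to_csv(args.results / f"auc_{design}.csv", index=False, float_format="%.10g")
        tables[design] = tab
        print(f"{design}: {len(tab)} AUCs written")

    merged = tables["lagged"].merge(tables["proximity"], on="item_id",
                                    suffixes=("_lag", "_prox"))
    distinct = merged[(merged["ci_hi_lag"] < merged["ci_lo_prox"])
                      | (merged["ci_hi_prox"] < merged["ci_lo_lag"])]
    print("items with non-overlapping lagged vs proximity 95% CIs:")
    for _, r in distinct.iterrows():
        print(f"  {r['item_id']:22s} lagged {r['auc_lag']:.2f} "
              f"[{r['ci_lo_lag']:.2f},{r['ci_hi_lag']:.2f}]  "
              f"proximity {r['auc_prox']:.2f} [{r['ci_lo_prox']:.2f},{r['ci_hi_prox']:.2f}]")


if __name__ == "__main__":
    main()
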