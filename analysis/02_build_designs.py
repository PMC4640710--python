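#!/usr/bin/env python
"""Restructure the panel into the lagged, proximity and static model datasets.

The lagged (predictive) design pairs each wave's ratings with violence in the
*following* window; the proximity (causal) design pairs ratings and violence
within the *same* window; the static design repeats the baseline historical
items against every observed window.
"""

import argparse
from pathlib import Path

from proxrisk.panel_io import read_panel
from proxrisk.windows import build_design


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    panel = read_panel(args.results / "panel.csv")
    for design in ("lagged", "proximity", "static"):
        ds = build_design(panel, design)
        out = args.results / f"model_{design}.csv"
        ds.data.to_csv(out, index=False, float_format="%.10g")
        print(f"{design:9s}: {ds.n_rows} rows, {ds.n_subjects} subjects, "
              f"{len(ds.exposure_columns)} exposures -> {out}")


if __name__ == "__main__":
    main()
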