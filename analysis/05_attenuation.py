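#!/usr/bin/env python
"""Explanatory-variable screening and attenuation ledgers, risk and protective.

Screens the dynamic risk items (clinical + risk management) and the
protective items for explanatory variables (independent effect on violence
AND correlation with the other factors), then refits every other significant
factor with the explanatory set added — singly and jointly — recording the
percentage change of each log-odds coefficient.  With the generator's
distal -> proximal -> violence wiring the jointly adjusted changes sit near
100% and the adjusted ORs near 1.
"""

import argparse
from pathlib import Path

import pandas as pd

from proxrisk.attenuation import attenuation_table, screen_explanatory
from proxrisk.items import scale_items
from proxrisk.panel_io import read_panel


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--levels", type=int, default=3)
    args = ap.parse_args()
    panel = read_panel(args.results / "panel.csv")

    sides = {"risk": scale_items(panel.catalogue, "C") + scale_items(panel.catalogue, "R"),
             "protective": scale_items(panel.catalogue, "SAPROF")}
    for side, cands in sides.items():
        screened, evidence = screen_explanatory(panel, cands, levels=args.levels)
        evidence.to_csv(args.results / f"screen_{side}.csv", index=False,
                        float_format="%.10g")
        print(f"{side}: explanatory variables = {screened or 'none'}")

        fits = args.results / "fits_proximity.csv"
        if not fits.exists():
            print(f"  (run 04_association_models.py first: {fits} missing)")
            continue
        tab = pd.read_csv(fits)
        base = [i for i in tab.loc[tab["p"] < 0.05, "item_id"]
                if i in cands and i not in screened]
        if not (base and screened):
            print(f"  attenuation skipped (base={base})")
            continue
        ledgers = attenuation_table(panel, base, screened, levels=args.levels)
        out = pd.concat([l.to_frame() for l in ledgers.values()], ignore_index=True)
        out.to_csv(args.results / f"attenuation_{side}.csv", index=False,
                   float_format="%.10g")
        full = out[out["model"] == "model_full"]
        print(f"  fully adjusted ({'+'.join(screened)}):")
        for _, r in full.iterrows():
            print(f"    {r['factor']:22s} AOR {r['adjusted_or']:.2f} "
                  f"[{r['ci_lo']:.2f},{r['ci_hi']:.2f}]  change {r['pct_change']:.1f}%")


if __name__ == "__main__":
    main()
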