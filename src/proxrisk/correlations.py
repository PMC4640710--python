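"""Pairwise Spearman correlation summaries within an instrument scale.

Mirrors the inter-item correlation audit of the analysis: all pairwise
Spearman coefficients among a scale's items at one wave, summarised by mean,
SD and median, with the count of pairs significant at a Bonferroni-corrected
alpha of 0.05 / (number of pairs).  Pairs involving a constant item have an
undefined coefficient; they are excluded from every summary and counted
separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortPanel
from .items import scale_items

__all__ = ["SpearmanSummary", "spearman_item_summary", "spearman_pairs"]


@dataclass
class SpearmanSummary:
    scale: str
    wave: str
    mean: float
    sd: float
    median: float
    n_significant: int
    n_pairs: int  # defined pairs entering the summary
    n_undefined: int
    alpha: float  # Bonferroni-corrected threshold actually applied
    pairs: pd.DataFrame  # item_a, item_b, rho, p, significant

    def __str__(self) -> str:  # "x # y" notation: significant out of total
        return (f"{self.scale}@{self.wave}: M={self.mean:.2f} SD={self.sd:.2f} "
                f"Md={self.median:.2f}  {self.n_significant} # {self.n_pairs}")


def spearman_pairs(panel: CohortPanel, items: list[str], wave: str) -> pd.DataFrame:
    """All pairwise Spearman coefficients among ``items`` at one wave."""
    df = panel.data[panel.data["wave"] == wave]
    rows = []
    for i, a in enumerate(items):
        for b in items[i + 1:]:
            xa, xb = df[a].to_numpy(), df[b].to_numpy()
            if len(xa) < 3 or xa.min() == xa.max() or xb.min() == xb.max():
                rows.append({"item_a": a, "item_b": b, "rho": np.nan, "p": np.nan})
                continue
            rho, p = stats.spearmanr(xa, xb)
            rows.append({"item_a": a, "item_b": b, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows)


def spearman_item_summary(panel: CohortPanel, scale: str, wave: str,
                          alpha: float = 0.05) -> SpearmanSummary:
    """Summary (M, SD, Md, significant count) of a scale's inter-item correlations."""
    items = [i for i in scale_items(panel.catalogue, scale) if i in panel.data.columns]
    if len(items) < 2:
        raise ValueError(f"need >=2 items on scale {scale!r}, found {len(items)}")
    if (panel.data["wave"] == wave).sum() == 0:
        raise ValueError(f"no rows at wave {wave!r}")
    pairs = spearman_pairs(panel, items, wave)
    n_total = len(pairs)
    alpha_bonf = alpha / n_total
    defined = pairs.dropna(subset=["rho"])
    n_undefined = n_total - len(defined)
    if n_undefined:
        warnings.warn(f"{n_undefined} pair(s) undefined (constant item) on {scale}@{wave}")
    pairs = pairs.assign(significant=pairs["p"] < alpha_bonf)
    rho = defined["rho"].to_numpy()
    return SpearmanSummary(
        scale=scale, wave=wave,
        mean=float(rho.mean()) if len(rho) else np.nan,
        sd=float(rho.std(ddof=1)) if len(rho) > 1 else np.nan,
        median=float(np.median(rho)) if len(rho) else np.nan,
        n_significant=int((defined["p"] < alpha_bonf).sum()),
        n_pairs=len(defined), n_undefined=n_undefined,
        alpha=alpha_bonf, pairs=pairs,
    )
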