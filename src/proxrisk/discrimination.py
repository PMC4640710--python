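"""Rank-based discrimination (AUC / Somers' D) with cluster-robust inference.

The point estimate is the probability that a randomly chosen violent row
outranks a randomly chosen non-violent row, counting ties as 1/2 — equal to
(Somers' D + 1)/2.  Because subjects contribute up to two windows, the
standard error comes from a leave-one-subject-out (grouped, delete-1)
jackknife, the 95% CI is the normal approximation truncated to [0, 1], and
the p-value tests AUC = 0.5.  Values below 0.5 indicate protective
(inverse) discrimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .windows import ModelDataset

__all__ = ["AUCResult", "auc_point", "auc_clustered", "compare_auc", "auc_table", "UndefinedAUCError"]


class UndefinedAUCError(ValueError):
    """AUC needs at least one case and one control."""


@dataclass
class AUCResult:
    item_id: str
    design: str
    auc: float
    se: float
    ci_lo: float
    ci_hi: float
    p: float
    n_pairs: int

    @property
    def has_ci(self) -> bool:
        return np.isfinite(self.ci_lo) and np.isfinite(self.ci_hi)


def auc_point(scores, outcomes) -> float:
    """Mann-Whitney AUC: P(case > control) + 0.5 * P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be 1-D and the same length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("need at least one case and one control")
    ranks = stats.rankdata(s)  # midranks handle ties
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auc_clustered(dataset: ModelDataset, item_id: str, alpha: float = 0.05) -> AUCResult:
    """Pooled AUC for one exposure with leave-one-subject-out jackknife inference."""
    df = dataset.data
    if item_id not in df.columns:
        raise KeyError(f"no exposure column {item_id!r} in dataset")
    s = df[item_id].to_numpy(dtype=float)
    y = df["outcome"].to_numpy()
    subj = df["subject_id"].to_numpy()
    est = auc_point(s, y)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    n_pairs = n1 * n0

    clusters = pd.unique(subj)
    if len(clusters) < 2:
        warnings.warn("fewer than 2 subject clusters: returning point estimate without CI")
        return AUCResult(item_id, dataset.design, est, np.nan, np.nan, np.nan, np.nan, n_pairs)

    reps = []
    for cl in clusters:
        keep = subj != cl
        yk = y[keep]
        if yk.min() == yk.max():  # deletion leaves a single class: replicate undefined
            continue
        reps.append(auc_point(s[keep], yk))
    g = len(reps)
    if g < 2:
        warnings.warn("jackknife degenerate (single informative cluster): no CI")
        return AUCResult(item_id, dataset.design, est, np.nan, np.nan, np.nan, np.nan, n_pairs)
    reps = np.asarray(reps)
    se = float(np.sqrt((g - 1) / g * np.sum((reps - reps.mean()) ** 2)))
    z = stats.norm.ppf(1 - alpha / 2)
    lo = max(0.0, est - z * se)
    hi = min(1.0, est + z * se)
    p = float(2 * stats.norm.sf(abs(est - 0.5) / se)) if se > 0 else (1.0 if est == 0.5 else 0.0)
    return AUCResult(item_id, dataset.design, est, se, lo, hi, p, n_pairs)


def compare_auc(a: AUCResult, b: AUCResult) -> str:
    """'distinct' iff the closed 95% CIs are disjoint; touching endpoints overlap."""
    if not (a.has_ci and b.has_ci):
        raise ValueError("both results must carry confidence intervals")
    return "distinct" if (a.ci_hi < b.ci_lo or b.ci_hi < a.ci_lo) else "overlapping"


def auc_table(dataset: ModelDataset, items: list[str] | None = None) -> pd.DataFrame:
    """AUC, 95% CI and p for every exposure column (or a chosen subset)."""
    items = items if items is not None else dataset.exposure_columns
    rows = []
    for iid in items:
        r = auc_clustered(dataset, iid)
        rows.append({"item_id": r.item_id, "design": r.design, "auc": r.auc, "se": r.se,
                     "ci_lo": r.ci_lo, "ci_hi": r.ci_hi, "p": r.p, "n_pairs": r.n_pairs})
    return pd.DataFrame(rows)
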