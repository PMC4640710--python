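"""Restructure a cohort panel into the competing exposure/outcome designs.

Two 6-month outcome windows exist: w1 (0-6 months, closed by the 6-month
assessment) and w2 (6-12 months, closed by the 12-month assessment).  Because
each assessment rates the *past* 6 months, the admissible pairings are:

lagged (predictive)
    exposures rated at the wave *opening* the window predict violence in it:
    baseline -> w1, m6 -> w2.
proximity (causal)
    exposures rated at the wave *closing* the window co-occur with violence:
    m6 <-> w1, m12 <-> w2.
static
    historical items, rated once at baseline, paired with every observed
    outcome window.

Ordinal item scores enter as numeric 0-2 (one odds ratio per 1-point
increase); scale totals as numeric per-point.  Covariates are always the
baseline values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import WINDOW_CLOSING_WAVE, CohortPanel, EmptyPanelError
from .items import total_score_column

__all__ = ["ModelDataset", "build_lagged", "build_proximity", "build_static", "build_design"]

#: design -> {window: exposure wave}
EXPOSURE_WAVE = {
    "lagged": {"w1": "baseline", "w2": "m6"},
    "proximity": {"w1": "m6", "w2": "m12"},
    "static": {"w1": "baseline", "w2": "baseline"},
}

_COVARIATES = ["age", "gender", "ethnicity", "diagnosis"]


@dataclass
class ModelDataset:
    """Long-format modelling rows: at most one row per subject x window.

    ``data`` columns: subject_id, trust_id, window, outcome, the baseline
    covariates, the exposure item columns and scale totals.
    """

    design: str
    data: pd.DataFrame
    exposure_columns: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique() if len(self.data) else 0

    @property
    def n_trusts(self) -> int:
        return self.data["trust_id"].nunique() if len(self.data) else 0

    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            return
        if df.duplicated(subset=["subject_id", "window"]).any():
            raise ValueError("duplicate subject x window rows")
        if df.groupby("subject_id").size().max() > 2:
            raise ValueError("more than two rows for a subject")
        if not df["outcome"].isin([0, 1]).all():
            raise ValueError("outcome must be binary")


def _build(panel: CohortPanel, design: str, item_ids: list[str], totals: dict[str, list[str]]) -> ModelDataset:
    if len(panel.data) == 0:
        raise EmptyPanelError("cannot build a model dataset from an empty panel")
    df = panel.data
    by_wave = {w: g.set_index("subject_id") for w, g in df.groupby("wave")}
    frames = []
    for window, exp_wave in EXPOSURE_WAVE[design].items():
        close_wave = WINDOW_CLOSING_WAVE[window]
        if exp_wave not in by_wave or close_wave not in by_wave:
            continue
        exp = by_wave[exp_wave]
        out = by_wave[close_wave]["violence_w"].dropna()
        common = exp.index.intersection(out.index)
        if len(common) == 0:
            continue
        exp = exp.loc[common]
        block = exp[["trust_id"] + _COVARIATES + item_ids].copy()
        block.insert(0, "window", window)
        block["outcome"] = out.loc[common].astype(int)
        frames.append(block.reset_index())
    if not frames:
        data = pd.DataFrame(columns=["subject_id", "trust_id", "window"] + _COVARIATES + item_ids + ["outcome"])
    else:
        data = pd.concat(frames, ignore_index=True)
    for tot_col, ids in totals.items():
        data[tot_col] = data[ids].sum(axis=1) if len(data) else pd.Series(dtype=int)
    data = data.sort_values(["subject_id", "window"]).reset_index(drop=True)
    ds = ModelDataset(design, data, exposure_columns=item_ids + list(totals))
    ds.validate()
    return ds


def _dynamic_ids(panel: CohortPanel) -> tuple[list[str], dict[str, list[str]]]:
    ids = [i for i in panel.item_columns if panel.catalogue[i].scale != "H"]
    totals = {}
    for scale in ("C", "R", "SAPROF"):
        sids = [i for i in ids if panel.catalogue[i].scale == scale]
        if sids:
            totals[total_score_column(scale)] = sids
    return ids, totals


def build_lagged(panel: CohortPanel) -> ModelDataset:
    """Predictive design: prior-wave dynamic ratings -> violence in the next window."""
    ids, totals = _dynamic_ids(panel)
    return _build(panel, "lagged", ids, totals)


def build_proximity(panel: CohortPanel) -> ModelDataset:
    """Causal design: dynamic ratings and violence within the same window."""
    ids, totals = _dynamic_ids(panel)
    return _build(panel, "proximity", ids, totals)


def build_static(panel: CohortPanel) -> ModelDataset:
    """Baseline historical items paired with every observed outcome window."""
    ids = [i for i in panel.item_columns if panel.catalogue[i].scale == "H"]
    totals = {total_score_column("H"): ids} if ids else {}
    return _build(panel, "static", ids, totals)


def build_design(panel: CohortPanel, design: str) -> ModelDataset:
    try:
        return {"lagged": build_lagged, "proximity": build_proximity, "static": build_static}[design](panel)
    except KeyError:
        raise ValueError(f"unknown design {design!r}") from None
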