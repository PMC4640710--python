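"""Read/write the panel CSV and its JSON sidecar.

Schema: one row per subject x observed wave with columns
``subject_id,trust_id,wave,age,gender,ethnicity,diagnosis,<item...>,violence_w``.
``violence_w`` holds the flag for the outcome window the row's wave closes and
is empty on baseline rows.  A sidecar ``<panel>.meta.json`` stores the item
catalogue and, for simulated panels, the generating configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortPanel
from .config import SimConfig, WAVES
from .items import ItemDef, default_catalogue

__all__ = ["read_panel", "write_panel", "PanelSchemaError", "sidecar_path"]

_BASE_COLUMNS = ["subject_id", "trust_id", "wave", "age", "gender", "ethnicity", "diagnosis"]


class PanelSchemaError(ValueError):
    """Panel file violates the documented CSV schema."""


def sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def write_panel(panel: CohortPanel, path) -> None:
    path = Path(path)
    df = panel.data.copy()
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {
        "catalogue": {iid: dataclasses.asdict(d) for iid, d in panel.catalogue.items()},
        "config": panel.provenance.to_dict() if isinstance(panel.provenance, SimConfig) else None,
        "provenance": "simulated" if isinstance(panel.provenance, SimConfig) else str(panel.provenance),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_panel(path) -> CohortPanel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)

    catalogue = default_catalogue()
    provenance: SimConfig | str = "external file"
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
        catalogue = {iid: ItemDef(**d) for iid, d in meta["catalogue"].items()}
        if meta.get("config") is not None:
            provenance = SimConfig.from_dict(meta["config"])

    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"missing required columns: {missing}")
    item_cols = [c for c in df.columns if c not in _BASE_COLUMNS and c != "violence_w"]
    unknown = [c for c in item_cols if c not in catalogue]
    if unknown:
        raise PanelSchemaError(f"unknown item columns: {unknown}")

    bad_wave = ~df["wave"].isin(WAVES)
    if bad_wave.any():
        raise PanelSchemaError(f"unknown wave at row {int(df.index[bad_wave][0])}")
    dup = df.duplicated(subset=["subject_id", "wave"])
    if dup.any():
        raise PanelSchemaError(f"duplicated subject x wave at row {int(df.index[dup][0])}")
    for col in item_cols:
        bad = ~df[col].isin([0, 1, 2])
        if bad.any():
            raise PanelSchemaError(
                f"score outside {{0,1,2}} in column {col!r} at row {int(df.index[bad][0])}"
            )
        df[col] = df[col].astype(np.int64)
    if "violence_w" not in df.columns:
        df["violence_w"] = np.nan
    flags = df["violence_w"].dropna()
    if not flags.isin([0.0, 1.0]).all():
        bad = df["violence_w"].notna() & ~df["violence_w"].isin([0.0, 1.0])
        raise PanelSchemaError(f"violence_w not in {{0,1}} at row {int(df.index[bad][0])}")

    panel = CohortPanel(df, catalogue, provenance)
    panel.validate()
    return panel
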