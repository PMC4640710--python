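"""Shared test helpers: hand-built tiny panels."""

import numpy as np
import pandas as pd

from proxrisk.cohort import CohortPanel
from proxrisk.items import default_catalogue

_COVARIATE_DEFAULTS = {"age": 40.0, "gender": "male", "ethnicity": "white",
                       "diagnosis": "schizophrenia_spectrum"}


def make_panel(subjects):
    """Hand-build a tiny CohortPanel.

    ``subjects`` is a list of dicts with keys: subject_id, trust_id,
    waves (dict wave -> {item_id: score} overrides; missing items default 0),
    violence (dict window -> 0/1), and optional covariate overrides.
    """
    cat = default_catalogue()
    rows = []
    for s in subjects:
        cov = {k: s.get(k, v) for k, v in _COVARIATE_DEFAULTS.items()}
        for wave, overrides in s["waves"].items():
            row = {"subject_id": s["subject_id"], "trust_id": s["trust_id"],
                   "wave": wave, **cov}
            for iid in cat:
                row[iid] = overrides.get(iid, 0)
            vio = s.get("violence", {})
            if wave == "m6":
                row["violence_w"] = float(vio["w1"]) if "w1" in vio else np.nan
            elif wave == "m12":
                row["violence_w"] = float(vio["w2"]) if "w2" in vio else np.nan
            else:
                row["violence_w"] = np.nan
            rows.append(row)
    return CohortPanel(pd.DataFrame(rows), cat, "external file")
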