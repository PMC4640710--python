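"""Synthetic discharge-cohort generator and panel container.

The generator produces one row per subject x observed wave with ordinal 0/1/2
item ratings for both instruments, baseline covariates, Trust membership, and
a binary violence flag per closed 6-month outcome window.

Latent dynamics
---------------
Every dynamic item ``i`` for subject ``s`` carries a stationary standard-normal
latent value evolving as AR(1) across the three waves:

    e[i, w] = sqrt(c) * g[w] + sqrt(1 - c) * a[i, w]

where ``g`` is a scale-group common factor and ``a[i]`` an item-specific
factor, both AR(1) with autocorrelation ``rho``; ``c = item_corr`` is the
cross-item latent correlation.  Proximal items additionally receive the
standardised mean of their group's distal latents scaled by ``delta_distal``
(then re-standardised), so distal factors act on violence only through the
proximal ones.  Thresholds map latents to {0, 1, 2}.

Violence in a window depends only on the proximal item *scores* at the wave
closing that window, plus Gaussian random intercepts for subject and Trust:

    logit P(violent) = baseline_logit (+ shift for window 2)
                       + sum_j gamma_j * score_j(closing wave)
                       + u_subject + u_trust

Historical items are drawn once and held fixed across waves.  Attrition is
missing-at-random and monotone: a subject seen at 12 months was seen at 6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    DIAGNOSIS_LEVELS,
    ETHNICITY_LEVELS,
    WAVES,
    WINDOWS,
    ConfigError,
    SimConfig,
)
from .items import ItemDef, default_catalogue

__all__ = ["CohortPanel", "generate_cohort", "panel_summary", "EmptyPanelError"]

#: wave whose assessment closes each outcome window
WINDOW_CLOSING_WAVE = {"w1": "m6", "w2": "m12"}


class EmptyPanelError(ValueError):
    """Operation requires a non-empty cohort panel."""


@dataclass
class CohortPanel:
    """Long-format cohort: one row per subject x observed wave.

    ``data`` columns: subject_id, trust_id, wave, age, gender, ethnicity,
    diagnosis, one column per catalogue item, and ``violence_w`` (the flag for
    the window the row's wave closes; NaN on baseline rows).
    """

    data: pd.DataFrame
    catalogue: dict[str, ItemDef] = field(default_factory=default_catalogue)
    provenance: SimConfig | str = "external file"

    @property
    def item_columns(self) -> list[str]:
        return [iid for iid in self.catalogue if iid in self.data.columns]

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique() if len(self.data) else 0

    @property
    def n_trusts(self) -> int:
        return self.data["trust_id"].nunique() if len(self.data) else 0

    def observed_waves(self, subject_id) -> list[str]:
        rows = self.data[self.data["subject_id"] == subject_id]
        return [w for w in WAVES if w in set(rows["wave"])]

    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            return
        unknown = [c for c in df.columns if c.startswith(("h_", "c_", "r_", "s_")) and c not in self.catalogue]
        if unknown:
            raise ValueError(f"item columns not in catalogue: {unknown}")
        dup = df.duplicated(subset=["subject_id", "wave"])
        if dup.any():
            raise ValueError(f"duplicated subject x wave at rows {list(df.index[dup])}")
        scores = df[self.item_columns]
        bad = ~scores.isin([0, 1, 2]).to_numpy()
        if bad.any():
            r = int(np.argwhere(bad)[0, 0])
            raise ValueError(f"item score outside {{0,1,2}} at row {df.index[r]}")


def _ar1_paths(rng: np.random.Generator, shape: tuple[int, ...], n_waves: int, rho: float) -> np.ndarray:
    """Stationary N(0,1) AR(1) paths; returned array has shape ``shape + (n_waves,)``."""
    out = np.empty(shape + (n_waves,))
    out[..., 0] = rng.standard_normal(shape)
    innov_sd = np.sqrt(1.0 - rho**2)
    for w in range(1, n_waves):
        out[..., w] = rho * out[..., w - 1] + innov_sd * rng.standard_normal(shape)
    return out


def _score(latent: np.ndarray, cuts: tuple[float, float]) -> np.ndarray:
    return (latent > cuts[0]).astype(np.int64) + (latent > cuts[1]).astype(np.int64)


def generate_cohort(config: SimConfig) -> CohortPanel:
    """Simulate a full cohort panel; deterministic for a fixed ``config.seed``."""
    config.validate()
    cat = default_catalogue()
    if config.n_subjects == 0:
        cols = ["subject_id", "trust_id", "wave", "age", "gender", "ethnicity", "diagnosis"]
        cols += list(cat) + ["violence_w"]
        return CohortPanel(pd.DataFrame(columns=cols), cat, config)

    rng = np.random.default_rng(config.seed)
    n, n_waves = config.n_subjects, len(WAVES)

    # Trust membership: balanced then shuffled, so every Trust is populated
    trust = np.arange(n) % config.n_trusts
    rng.shuffle(trust)

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 75.0).round(1)
    gender = np.where(rng.random(n) < config.p_female, "female", "male")
    ethnicity = rng.choice(ETHNICITY_LEVELS, size=n, p=np.asarray(config.ethnicity_probs))
    diagnosis = rng.choice(DIAGNOSIS_LEVELS, size=n, p=np.asarray(config.diagnosis_probs))

    u_trust = rng.normal(0.0, config.sigma_trust, config.n_trusts)
    u_subj = rng.normal(0.0, config.sigma_subject, n)

    # --- latent construction ------------------------------------------------
    c = config.item_corr
    groups = {
        "H": [i for i, d in cat.items() if d.scale == "H"],
        "risk_dyn": [i for i, d in cat.items() if d.scale in ("C", "R")],
        "SAPROF": [i for i, d in cat.items() if d.scale == "SAPROF"],
    }
    latents: dict[str, np.ndarray] = {}  # item -> (n, n_waves)
    for gname, iids in groups.items():
        g = _ar1_paths(rng, (n,), n_waves, config.rho)
        for iid in iids:
            a = _ar1_paths(rng, (n,), n_waves, config.rho)
            latents[iid] = np.sqrt(c) * g + np.sqrt(1.0 - c) * a

    def couple_proximal(prox_ids: list[str], distal_ids: list[str]) -> None:
        """Mix the standardised distal mean into each proximal latent; keep N(0,1)."""
        d = config.delta_distal
        if d == 0.0 or not distal_ids:
            return
        k = len(distal_ids)
        mean_d = np.mean([latents[i] for i in distal_ids], axis=0)
        sd_mean = np.sqrt(c + (1.0 - c) / k)
        dbar = mean_d / sd_mean  # standardised distal composite, cov with e_p = c/sd_mean
        cov = c / sd_mean
        norm = np.sqrt(1.0 + d * d + 2.0 * d * cov)
        for iid in prox_ids:
            latents[iid] = (latents[iid] + d * dbar) / norm

    couple_proximal(
        [i for i, dd in cat.items() if dd.scale in ("C", "R") and dd.role == "proximal"],
        [i for i, dd in cat.items() if dd.scale in ("C", "R") and dd.role == "distal"],
    )
    couple_proximal(
        ["s_self_control"],
        [i for i, dd in cat.items() if dd.scale == "SAPROF" and dd.role == "protective"],
    )

    scores: dict[str, np.ndarray] = {}
    for iid, d in cat.items():
        cuts = config.item_thresholds[iid]
        if d.role == "static":
            s = _score(latents[iid][:, 0], cuts)
            scores[iid] = np.repeat(s[:, None], n_waves, axis=1)
        else:
            scores[iid] = _score(latents[iid], cuts)

    # --- violence per window ------------------------------------------------
    violence = {}
    for widx, window in enumerate(WINDOWS):
        close = WAVES.index(WINDOW_CLOSING_WAVE[window])
        eta = np.full(n, config.baseline_logit + (config.window2_logit_shift if window == "w2" else 0.0))
        for iid, gamma in config.gamma_proximal.items():
            eta += gamma * scores[iid][:, close]
        eta += u_subj + u_trust[trust]
        p = 1.0 / (1.0 + np.exp(-eta))
        violence[window] = (rng.random(n) < p).astype(np.int64)

    # --- attrition (monotone, missing at random) ----------------------------
    obs_m6 = rng.random(n) < config.retention_m6
    obs_m12 = obs_m6 & (rng.random(n) < config.retention_m12)
    observed = {"baseline": np.ones(n, bool), "m6": obs_m6, "m12": obs_m12}

    frames = []
    for widx, wave in enumerate(WAVES):
        mask = observed[wave]
        row = {
            "subject_id": np.arange(1, n + 1)[mask],
            "trust_id": trust[mask] + 1,
            "wave": wave,
            "age": age[mask],
            "gender": gender[mask],
            "ethnicity": ethnicity[mask],
            "diagnosis": diagnosis[mask],
        }
        for iid in cat:
            row[iid] = scores[iid][mask, widx]
        if wave == "baseline":
            row["violence_w"] = np.nan
        else:
            window = "w1" if wave == "m6" else "w2"
            row["violence_w"] = violence[window][mask].astype(float)
        frames.append(pd.DataFrame(row))

    df = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["subject_id", "wave"], key=lambda s: s.map({w: i for i, w in enumerate(WAVES)}) if s.name == "wave" else s)
        .reset_index(drop=True)
    )
    panel = CohortPanel(df, cat, config)
    panel.validate()
    return panel


def panel_summary(panel: CohortPanel) -> dict:
    """Descriptive summary: window prevalences, wave completion, covariate and
    item-score distributions."""
    df = panel.data
    if len(df) == 0:
        raise EmptyPanelError("cannot summarise an empty panel")
    n = panel.n_subjects
    out: dict = {"n_subjects": n, "n_trusts": panel.n_trusts}

    prev = {}
    for window, wave in WINDOW_CLOSING_WAVE.items():
        flags = df.loc[df["wave"] == wave, "violence_w"].dropna()
        prev[window] = {"n": int(len(flags)), "n_violent": int(flags.sum()),
                        "prevalence": float(flags.mean()) if len(flags) else np.nan}
    out["violence"] = prev

    out["completion"] = {
        wave: {"n": int((df["wave"] == wave).sum()),
               "fraction": float((df["wave"] == wave).sum() / n)}
        for wave in WAVES
    }

    base = df[df["wave"] == "baseline"]
    out["covariates"] = {
        "age_mean": float(base["age"].mean()),
        "age_sd": float(base["age"].std(ddof=1)) if len(base) > 1 else 0.0,
        "p_female": float((base["gender"] == "female").mean()),
        "ethnicity": base["ethnicity"].value_counts(normalize=True).to_dict(),
        "diagnosis": base["diagnosis"].value_counts(normalize=True).to_dict(),
    }

    item_rows = []
    for iid in panel.item_columns:
        for wave in WAVES:
            s = df.loc[df["wave"] == wave, iid]
            if len(s) == 0:
                continue
            item_rows.append({
                "item_id": iid, "wave": wave, "mean": float(s.mean()),
                "p0": float((s == 0).mean()), "p1": float((s == 1).mean()),
                "p2": float((s == 2).mean()),
            })
    out["item_scores"] = pd.DataFrame(item_rows)
    return out
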