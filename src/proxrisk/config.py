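"""Simulation configuration for the synthetic discharge cohort.

Defaults are calibrated to the descriptive statistics of the study population
the generator emulates: ~409 patients discharged from medium secure services
across 26 NHS Trusts, mean age 37.8 (SD 9.7), 11.1% women, 80.9%
schizophrenia-spectrum primary diagnosis, three assessment waves (baseline,
6 and 12 months) with retention 95% at 6 months and 89% (conditional) at 12
months, and 6-month violence prevalences of ~14.0% (first window) and ~12.5%
(second window).

Per-item prevalences of the 0/1/2 ratings are not published anywhere; the
default latent thresholds are an arbitrary calibration chosen to give
plausible score distributions for a forensic population and are documented as
such in the methods note.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .items import default_catalogue

__all__ = ["SimConfig", "ConfigError", "default_config", "load_config", "save_config"]

ETHNICITY_LEVELS = ("white", "black", "asian", "mixed_other")
DIAGNOSIS_LEVELS = ("schizophrenia_spectrum", "other")
WAVES = ("baseline", "m6", "m12")
WINDOWS = ("w1", "w2")


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the offending field."""


def _default_gamma() -> dict[str, float]:
    # log-odds per 1-point score increase for the proximal items, ballpark of the
    # conditional (simultaneous-entry) causal estimates the design targets
    return {
        "c_violent_ideation": 1.20,
        "c_instability": 0.85,
        "r_stress_coping": 1.15,
        "s_self_control": -1.50,
    }


def _default_thresholds() -> dict[str, tuple[float, float]]:
    """Latent-normal cutpoints mapping N(0,1) scores to {0,1,2} per item.

    Historical items skew high (a forensic cohort has dense histories),
    dynamic risk items skew low-to-middle, protective items sit mid-scale.
    """
    cat = default_catalogue()
    out: dict[str, tuple[float, float]] = {}
    for iid, d in cat.items():
        if d.scale == "H":
            out[iid] = (-1.0, 0.0)
        elif d.scale in ("C", "R"):
            out[iid] = (0.25, 1.25)
        else:  # SAPROF
            out[iid] = (-1.0, 0.25)
    return out


@dataclass
class SimConfig:
    """Parameters of the synthetic-cohort generator.

    The causal wiring is distal -> proximal -> violence with no direct
    distal path: ``delta_distal`` couples the (standardised) mean of the
    distal latents into each proximal item's latent at the same wave, and
    ``gamma_proximal`` maps proximal item *scores* at the wave closing an
    outcome window onto the violence log-odds.
    """

    n_trusts: int = 26
    n_subjects: int = 409
    age_mean: float = 37.8
    age_sd: float = 9.7
    p_female: float = 0.111
    ethnicity_probs: tuple[float, ...] = (0.601, 0.254, 0.062, 0.083)
    diagnosis_probs: tuple[float, ...] = (0.809, 0.191)
    sigma_subject: float = 0.5
    sigma_trust: float = 0.3
    item_thresholds: dict[str, tuple[float, float]] = field(default_factory=_default_thresholds)
    rho: float = 0.4
    item_corr: float = 0.3
    gamma_proximal: dict[str, float] = field(default_factory=_default_gamma)
    delta_distal: float = 1.0
    baseline_logit: float = -2.90
    window2_logit_shift: float = -0.22
    retention_m6: float = 0.95
    retention_m12: float = 0.89
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        cat = default_catalogue()
        for name in ("n_trusts", "n_subjects"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_subjects > 0 and self.n_trusts == 0:
            raise ConfigError("n_trusts must be positive when n_subjects > 0")
        if self.age_sd < 0:
            raise ConfigError(f"age_sd must be >= 0, got {self.age_sd}")
        if not 0.0 <= self.p_female <= 1.0:
            raise ConfigError(f"p_female must lie in [0, 1], got {self.p_female}")
        for name, probs, levels in (
            ("ethnicity_probs", self.ethnicity_probs, ETHNICITY_LEVELS),
            ("diagnosis_probs", self.diagnosis_probs, DIAGNOSIS_LEVELS),
        ):
            p = np.asarray(probs, dtype=float)
            if len(p) != len(levels):
                raise ConfigError(f"{name} must have {len(levels)} entries, got {len(p)}")
            if (p < 0).any():
                raise ConfigError(f"{name} has negative entries")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ConfigError(f"{name} must sum to 1 within 1e-12, sums to {p.sum()!r}")
        for name in ("sigma_subject", "sigma_trust"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError(f"rho must lie in [0, 1), got {self.rho}")
        if not 0.0 <= self.item_corr < 1.0:
            raise ConfigError(f"item_corr must lie in [0, 1), got {self.item_corr}")
        for name in ("retention_m6", "retention_m12"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for iid, cuts in self.item_thresholds.items():
            if iid not in cat:
                raise ConfigError(f"item_thresholds refers to unknown item {iid!r}")
            if len(cuts) != 2 or not cuts[0] < cuts[1]:
                raise ConfigError(
                    f"item_thresholds[{iid!r}] must be two strictly increasing cutpoints, got {cuts!r}"
                )
        missing = set(cat) - set(self.item_thresholds)
        if missing:
            raise ConfigError(f"item_thresholds missing items: {sorted(missing)}")
        for iid in self.gamma_proximal:
            if iid not in cat:
                raise ConfigError(f"gamma_proximal refers to unknown item {iid!r}")
            if cat[iid].role != "proximal":
                raise ConfigError(f"gamma_proximal item {iid!r} is not a proximal item")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ethnicity_probs"] = list(self.ethnicity_probs)
        d["diagnosis_probs"] = list(self.diagnosis_probs)
        d["item_thresholds"] = {k: list(v) for k, v in self.item_thresholds.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "ethnicity_probs" in d:
            d["ethnicity_probs"] = tuple(d["ethnicity_probs"])
        if "diagnosis_probs" in d:
            d["diagnosis_probs"] = tuple(d["diagnosis_probs"])
        if "item_thresholds" in d:
            d["item_thresholds"] = {k: tuple(v) for k, v in d["item_thresholds"].items()}
        return cls(**d)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def default_config(**overrides) -> SimConfig:
    cfg = SimConfig(**overrides) if overrides else SimConfig()
    cfg.validate()
    return cfg


def load_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = SimConfig.from_dict(data)
    cfg.validate()
    return cfg


def save_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
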