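"""Explanatory-variable screening and coefficient-attenuation analysis.

A dynamic factor qualifies as *explanatory* when it is associated, at alpha
< 0.05, both with the violent outcome and with the other risk/protective
factors.  The outcome leg is judged by the multilevel logistic model — by
default the simultaneous-entry fit of all candidates, keeping those with
independent effects; a ``mode="marginal"`` switch screens on one-at-a-time
fits instead.  The exposure leg is a pairwise Spearman test between the
candidate and each other factor on the same design rows.

Attenuation of a base factor's association with violence after adding an
explanatory set is quantified on the log-odds scale:

    pct_change = 100 * (beta_unadjusted - beta_adjusted) / beta_unadjusted

where ``beta_unadjusted`` comes from the factor's own covariate-adjusted
causal model and ``beta_adjusted`` from the same model with the explanatory
set added.  Values above 100 occur when the adjusted odds ratio crosses 1;
the formula is sign-preserving for protective (negative-beta) factors.  No
mediation estimand is implied: temporal ordering within a window is unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortPanel
from .glmm import FitResult, SeparationWarning, fit_mixed_logit
from .windows import ModelDataset, build_design

__all__ = [
    "AttenuationRecord",
    "AttenuationLedger",
    "UndefinedAttenuationError",
    "pct_change",
    "screen_explanatory",
    "attenuation_table",
]


class UndefinedAttenuationError(ZeroDivisionError):
    """Attenuation is undefined when the unadjusted coefficient is zero."""


def pct_change(beta_unadjusted: float, beta_adjusted: float) -> float:
    """Percentage reduction of a log-odds coefficient after adjustment."""
    if beta_unadjusted == 0:
        raise UndefinedAttenuationError("beta_unadjusted is zero; attenuation undefined")
    return 100.0 * (beta_unadjusted - beta_adjusted) / beta_unadjusted


@dataclass
class AttenuationRecord:
    factor: str
    explanatory_set: tuple[str, ...]
    beta_unadjusted: float
    beta_adjusted: float
    pct_change: float
    adjusted_or: float
    adjusted_ci: tuple[float, float]
    adjusted_p: float
    converged: bool = True


@dataclass
class AttenuationLedger:
    model_id: str
    records: list[AttenuationRecord]
    explanatory_variables: tuple[str, ...]

    def validate(self) -> None:
        for r in self.records:
            if not set(r.explanatory_set) <= set(self.explanatory_variables):
                raise ValueError(f"record {r.factor}: explanatory_set outside ledger set")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"model": self.model_id, "factor": r.factor,
             "explanatory_set": "+".join(r.explanatory_set),
             "beta_unadjusted": r.beta_unadjusted, "beta_adjusted": r.beta_adjusted,
             "pct_change": r.pct_change, "adjusted_or": r.adjusted_or,
             "ci_lo": r.adjusted_ci[0], "ci_hi": r.adjusted_ci[1],
             "p": r.adjusted_p, "converged": r.converged}
            for r in self.records
        ])


def _quiet_fit(*args, **kw) -> FitResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        return fit_mixed_logit(*args, **kw)


def screen_explanatory(panel: CohortPanel, candidate_items: list[str],
                       design: str = "proximity", mode: str = "independent",
                       levels: int = 3, adjust: bool = True, alpha: float = 0.05,
                       n_quad: int = 7) -> tuple[list[str], pd.DataFrame]:
    """Select explanatory variables among ``candidate_items``.

    Returns ``(screened, evidence)`` where ``evidence`` records, per
    candidate, the violence-association p-value, the smallest Spearman
    p-value against the other candidates, and the two pass flags.  An empty
    screened set is a legitimate outcome, not an error.
    """
    if mode not in ("independent", "marginal"):
        raise ValueError("mode must be 'independent' or 'marginal'")
    dataset = build_design(panel, design)

    p_violence: dict[str, float] = {}
    if mode == "independent":
        fr = _quiet_fit(dataset, candidate_items, adjust=adjust, levels=levels, n_quad=n_quad)
        for iid in candidate_items:
            p_violence[iid] = fr.terms[iid].p
    else:
        for iid in candidate_items:
            fr = _quiet_fit(dataset, [iid], adjust=adjust, levels=levels, n_quad=n_quad)
            p_violence[iid] = fr.terms[iid].p

    rows = []
    screened = []
    df = dataset.data
    for iid in candidate_items:
        p_exp = np.inf
        x = df[iid].to_numpy(dtype=float)
        for other in candidate_items:
            if other == iid:
                continue
            z = df[other].to_numpy(dtype=float)
            if x.min() == x.max() or z.min() == z.max():
                continue
            if np.array_equal(x, z):  # perfect collinearity: association beyond doubt
                p_exp = 0.0
                continue
            _, p = stats.spearmanr(x, z)
            p_exp = min(p_exp, float(p))
        pass_out = bool(np.isfinite(p_violence[iid]) and p_violence[iid] < alpha)
        pass_exp = bool(p_exp < alpha)
        if pass_out and pass_exp:
            screened.append(iid)
        rows.append({"candidate": iid, "p_violence": p_violence[iid],
                     "min_p_exposure": p_exp if np.isfinite(p_exp) else np.nan,
                     "passes_outcome": pass_out, "passes_exposure": pass_exp,
                     "selected": pass_out and pass_exp})
    return screened, pd.DataFrame(rows)


def attenuation_table(panel: CohortPanel, base_factors: list[str],
                      explanatory_variables: list[str], design: str = "proximity",
                      levels: int = 3, adjust: bool = True, n_quad: int = 7,
                      include_model0: bool = True,
                      include_singles: bool = True) -> dict[str, AttenuationLedger]:
    """Full attenuation workflow over one design.

    For every base factor the unadjusted coefficient comes from its own
    covariate-adjusted model.  ``model0`` (optional) enters base and
    explanatory factors simultaneously (no attenuation defined there);
    ``model<k>`` adds the k-th explanatory variable alone; ``model_full``
    adds them all.  Non-convergent refits are flagged, never dropped.
    """
    dataset = build_design(panel, design)
    explanatory_variables = list(explanatory_variables)
    base_factors = [f for f in base_factors if f not in explanatory_variables]

    beta_u: dict[str, float] = {}
    for f in base_factors:
        fr = _quiet_fit(dataset, [f], adjust=adjust, levels=levels, n_quad=n_quad)
        beta_u[f] = fr.terms[f].beta

    ledgers: dict[str, AttenuationLedger] = {}

    if include_model0 and explanatory_variables:
        all_terms = base_factors + explanatory_variables
        fr = _quiet_fit(dataset, all_terms, adjust=adjust, levels=levels, n_quad=n_quad)
        recs = [
            AttenuationRecord(t, tuple(explanatory_variables), np.nan,
                              fr.terms[t].beta, np.nan, fr.terms[t].or_,
                              (fr.terms[t].ci_lo, fr.terms[t].ci_hi),
                              fr.terms[t].p, fr.converged)
            for t in all_terms
        ]
        ledgers["model0"] = AttenuationLedger("model0", recs, tuple(explanatory_variables))

    def adjusted_ledger(model_id: str, expl: list[str]) -> AttenuationLedger:
        recs = []
        for f in base_factors:
            if not expl:  # nothing added: the adjusted model is the baseline model
                recs.append(AttenuationRecord(f, (), beta_u[f], beta_u[f], 0.0,
                                              float(np.exp(beta_u[f])), (np.nan, np.nan),
                                              np.nan, True))
                continue
            try:
                fr = _quiet_fit(dataset, [f] + expl, adjust=adjust, levels=levels, n_quad=n_quad)
                e = fr.terms[f]
                recs.append(AttenuationRecord(
                    f, tuple(expl), beta_u[f], e.beta, pct_change(beta_u[f], e.beta),
                    e.or_, (e.ci_lo, e.ci_hi), e.p, fr.converged))
            except Exception as exc:
                warnings.warn(f"refit failed for {f} + {expl}: {exc}")
                recs.append(AttenuationRecord(f, tuple(expl), beta_u[f], np.nan, np.nan,
                                              np.nan, (np.nan, np.nan), np.nan, False))
        return AttenuationLedger(model_id, recs, tuple(explanatory_variables))

    if explanatory_variables and include_singles:
        for k, e in enumerate(explanatory_variables, start=1):
            ledgers[f"model{k}"] = adjusted_ledger(f"model{k}", [e])
    ledgers["model_full"] = adjusted_ledger("model_full", explanatory_variables)
    for led in ledgers.values():
        led.validate()
    return ledgers
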