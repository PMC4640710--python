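"""Nested random-intercept logistic regression via adaptive Gauss-Hermite quadrature.

Fits, by maximum likelihood, models of the form

    logit P(y_ij = 1) = x_ij' beta + u_subject(i) [+ u_trust(t(i))]

with u_subject ~ N(0, var_subject) and, for 3-level fits, u_trust ~
N(0, var_trust), subjects nested in Trusts.  The marginal likelihood is
integrated numerically: an adaptive Gauss-Hermite rule per subject (nodes
recentred at the conditional mode and rescaled by the conditional curvature,
found by Newton steps) nested inside an adaptive rule per Trust, whose mode
search uses posterior-expectation derivatives of the inner integrals.  Both
levels share a configurable node count (default 7).  With a variance at
zero the corresponding level collapses exactly to the unintegrated
likelihood, so a 3-level fit with var_trust = 0 equals the 2-level fit and a
fit with both variances zero equals ordinary pooled logistic regression.

Inference is Wald throughout: standard errors from the numerically
differentiated observed information at the optimum, 95% CIs and two-sided
p-values on the log-odds scale, odds ratios by exponentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit

from .windows import ModelDataset

__all__ = [
    "TermEstimate",
    "FitResult",
    "FitError",
    "SeparationWarning",
    "fit_mixed_logit",
    "fit_item_table",
]

_SQRT2 = np.sqrt(2.0)


class FitError(ValueError):
    """Model cannot be fitted on this dataset (bad outcome or design matrix)."""


class SeparationWarning(UserWarning):
    """A term shows signs of (quasi-)complete separation."""


@dataclass
class TermEstimate:
    beta: float
    se: float
    or_: float
    ci_lo: float
    ci_hi: float
    p: float


@dataclass
class FitResult:
    design: str
    terms: dict[str, TermEstimate]
    var_subject: float
    var_trust: float
    converged: bool
    n_rows: int
    loglik: float
    n_quad: int
    levels: int
    message: str = ""
    warnings: list[str] = field(default_factory=list)

    def term(self, name: str) -> TermEstimate:
        return self.terms[name]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "beta": e.beta, "se": e.se, "or": e.or_,
             "ci_lo": e.ci_lo, "ci_hi": e.ci_hi, "p": e.p}
            for t, e in self.terms.items()
        ]
        df = pd.DataFrame(rows)
        df["var_subject"] = self.var_subject
        df["var_trust"] = self.var_trust
        df["converged"] = self.converged
        return df


def _log1pexp(x):
    return np.logaddexp(0.0, x)


class _NestedLogitLikelihood:
    """Marginal log-likelihood machinery; rows sorted by (trust, subject)."""

    def __init__(self, X, y, subj_of_row, trust_of_subj, n_quad=7,
                 inner_iters=8, outer_iters=6):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.subj_of_row = np.asarray(subj_of_row)
        self.trust_of_subj = np.asarray(trust_of_subj)
        self.S = int(self.subj_of_row.max()) + 1
        self.T = int(self.trust_of_subj.max()) + 1
        # first-row index of each subject (rows contiguous per subject)
        first = np.ones(len(self.y), dtype=bool)
        first[1:] = self.subj_of_row[1:] != self.subj_of_row[:-1]
        self.row_starts = np.flatnonzero(first)
        z, w = np.polynomial.hermite.hermgauss(n_quad)
        self.z = z
        self.logw_plus = np.log(w) + z**2  # for the adaptive change of variables
        self.inner_iters = inner_iters
        self.outer_iters = outer_iters

    # -- subject level -------------------------------------------------------

    def _subject(self, beta, sigma_s, a_subj, need_derivs=False):
        """Per-subject log marginal likelihood given trust offsets ``a_subj``.

        With ``need_derivs``, also returns the first and second derivatives of
        each subject's log marginal with respect to its trust offset
        (posterior expectations over the quadrature nodes).
        """
        y, subj, S = self.y, self.subj_of_row, self.S
        eta0 = self.X @ beta + a_subj[subj]
        if sigma_s < 1e-8:
            p = expit(eta0)
            rowll = y * eta0 - _log1pexp(eta0)
            lm = np.bincount(subj, rowll, minlength=S)
            if not need_derivs:
                return lm
            d1 = np.bincount(subj, y - p, minlength=S)
            d2 = -np.bincount(subj, p * (1.0 - p), minlength=S)
            return lm, d1, d2

        inv_v = 1.0 / sigma_s**2
        u = np.zeros(S)
        h = np.full(S, -inv_v)
        for _ in range(self.inner_iters):
            eta = eta0 + u[subj]
            p = expit(eta)
            g = -u * inv_v + np.bincount(subj, y - p, minlength=S)
            h = -inv_v - np.bincount(subj, p * (1.0 - p), minlength=S)
            u -= np.clip(g / h, -5.0, 5.0)
        tau = 1.0 / np.sqrt(-h)

        U = u[:, None] + _SQRT2 * tau[:, None] * self.z[None, :]  # (S, K)
        ETA = eta0[:, None] + U[subj]  # (n, K)
        ROW = y[:, None] * ETA - _log1pexp(ETA)
        LL = np.add.reduceat(ROW, self.row_starts, axis=0)  # (S, K)
        F = -0.5 * np.log(2.0 * np.pi * sigma_s**2) - U**2 * (0.5 * inv_v) + LL
        A = self.logw_plus[None, :] + F
        m = A.max(axis=1)
        expA = np.exp(A - m[:, None])
        sumA = expA.sum(axis=1)
        lm = np.log(_SQRT2 * tau) + m + np.log(sumA)
        if not need_derivs:
            return lm
        W = expA / sumA[:, None]  # posterior node weights
        P = expit(ETA)
        S1 = np.add.reduceat(y[:, None] - P, self.row_starts, axis=0)
        S2 = np.add.reduceat(P * (1.0 - P), self.row_starts, axis=0)
        d1 = (W * S1).sum(axis=1)
        d2 = (W * (S1 * S1 - S2)).sum(axis=1) - d1**2
        return lm, d1, d2

    # -- trust level ---------------------------------------------------------

    def loglik(self, beta, sigma_s, sigma_t):
        if sigma_t < 1e-8:
            return float(self._subject(beta, sigma_s, np.zeros(self.S)).sum())
        T, tr = self.T, self.trust_of_subj
        inv_v = 1.0 / sigma_t**2
        a = np.zeros(T)
        G2 = np.full(T, -inv_v)
        for _ in range(self.outer_iters):
            lm, d1, d2 = self._subject(beta, sigma_s, a[tr], need_derivs=True)
            G1 = -a * inv_v + np.bincount(tr, d1, minlength=T)
            G2 = -inv_v + np.bincount(tr, d2, minlength=T)
            G2 = np.minimum(G2, -1e-8)
            a -= np.clip(G1 / G2, -5.0, 5.0)
        tau = 1.0 / np.sqrt(-G2)

        K = len(self.z)
        H = np.empty((T, K))
        for k in range(K):
            ak = a + _SQRT2 * tau * self.z[k]
            lm = self._subject(beta, sigma_s, ak[tr])
            H[:, k] = (-0.5 * np.log(2.0 * np.pi * sigma_t**2) - ak**2 * (0.5 * inv_v)
                       + np.bincount(tr, lm, minlength=T))
        A = self.logw_plus[None, :] + H
        m = A.max(axis=1)
        lt = np.log(_SQRT2 * tau) + m + np.log(np.exp(A - m[:, None]).sum(axis=1))
        return float(lt.sum())


# -- design matrix -----------------------------------------------------------

_ETHNICITY_DUMMIES = ("black", "asian", "mixed_other")


def build_design_matrix(dataset: ModelDataset, exposure_terms, adjust: bool,
                        extra_terms=()) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Fixed-effect design matrix: intercept, numeric exposures, and (if
    ``adjust``) baseline covariates with reference levels male / white /
    schizophrenia-spectrum.  Returns (X, names, sorted data)."""
    df = dataset.data.sort_values(["trust_id", "subject_id", "window"]).reset_index(drop=True)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    for t in exposure_terms:
        if t not in df.columns:
            raise FitError(f"exposure column {t!r} not in dataset")
        v = df[t].to_numpy(dtype=float)
        if len(df) and v.min() == v.max():
            raise FitError(f"exposure {t!r} is constant; cannot estimate its effect")
        cols[t] = v
    if adjust:
        cols["age"] = df["age"].to_numpy(dtype=float) - float(df["age"].mean())
        cols["gender[female]"] = (df["gender"] == "female").to_numpy(dtype=float)
        for lev in _ETHNICITY_DUMMIES:
            v = (df["ethnicity"] == lev).to_numpy(dtype=float)
            if v.any():
                cols[f"ethnicity[{lev}]"] = v
        v = (df["diagnosis"] == "other").to_numpy(dtype=float)
        if v.any():
            cols["diagnosis[other]"] = v
    for t in extra_terms:
        if t == "window":
            cols["window[w2]"] = (df["window"] == "w2").to_numpy(dtype=float)
        else:
            cols[t] = df[t].to_numpy(dtype=float)
    # drop degenerate covariate columns (all equal) other than the intercept
    names, arrays = [], []
    for name, v in cols.items():
        if name != "intercept" and len(df) and v.min() == v.max():
            continue
        names.append(name)
        arrays.append(v)
    X = np.column_stack(arrays) if arrays else np.empty((len(df), 0))
    return X, names, df


# -- fitting -----------------------------------------------------------------

def fit_mixed_logit(dataset: ModelDataset, exposure_terms, adjust: bool = True,
                    levels: int = 3, n_quad: int = 7, extra_terms=(),
                    max_iter: int = 300) -> FitResult:
    """ML fit of the nested random-intercept logistic model.

    Parameters
    ----------
    exposure_terms
        Column names entering as numeric fixed effects of interest.
    adjust
        Add the baseline covariates (age, gender, ethnicity, diagnosis).
    levels
        2 = rows within subjects; 3 = rows within subjects within Trusts.
    n_quad
        Gauss-Hermite node count at each level.
    """
    if levels not in (2, 3):
        raise ValueError("levels must be 2 or 3")
    if isinstance(exposure_terms, str):
        exposure_terms = [exposure_terms]
    exposure_terms = list(exposure_terms)
    if dataset.n_rows == 0:
        raise FitError("empty dataset")
    y_all = dataset.data["outcome"].to_numpy()
    if y_all.min() == y_all.max():
        raise FitError("outcome has a single class")

    X, names, df = build_design_matrix(dataset, exposure_terms, adjust, extra_terms)
    y = df["outcome"].to_numpy(dtype=float)
    subj_of_row, subj_index = pd.factorize(df["subject_id"])  # order of appearance = trust-sorted
    first_rows = np.flatnonzero(np.r_[True, subj_of_row[1:] != subj_of_row[:-1]])
    trust_of_subj, _ = pd.factorize(df["trust_id"].to_numpy()[first_rows])

    lik = _NestedLogitLikelihood(X, y, subj_of_row, trust_of_subj, n_quad=n_quad)
    p = X.shape[1]

    # warm start from a pooled logistic fit
    beta0 = np.zeros(p)
    beta0[0] = float(np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
        if np.all(np.isfinite(glm.params)) and np.abs(glm.params).max() < 20:
            beta0 = np.asarray(glm.params)
    except Exception:
        pass

    n_sigma = 2 if levels == 3 else 1
    x0 = np.r_[beta0, [0.4] * n_sigma]
    bounds = [(None, None)] * p + [(0.0, 8.0)] * n_sigma

    def unpack(x):
        beta = x[:p]
        sigma_s = x[p]
        sigma_t = x[p + 1] if levels == 3 else 0.0
        return beta, sigma_s, sigma_t

    def nll(x):
        beta, ss, st = unpack(x)
        return -lik.loglik(beta, ss, st)

    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": max_iter, "ftol": 1e-10},
                            jac=None)
    xhat = res.x
    loglik = -float(res.fun)
    beta_hat, ss_hat, st_hat = unpack(xhat)

    # observed information by central differences over the active parameters
    active = list(range(p))
    for j in range(p, len(xhat)):
        if xhat[j] > 1e-4:
            active.append(j)
    cov = _wald_cov(nll, xhat, active)

    fit_warnings: list[str] = []
    terms: dict[str, TermEstimate] = {}
    zcrit = stats.norm.ppf(0.975)
    for j, name in enumerate(names):
        b = float(beta_hat[j])
        se = float(np.sqrt(cov[j, j])) if np.isfinite(cov[j, j]) and cov[j, j] > 0 else np.nan
        if np.isfinite(se):
            lo, hi = b - zcrit * se, b + zcrit * se
            pval = float(2 * stats.norm.sf(abs(b) / se)) if se > 0 else np.nan
        else:
            lo = hi = pval = np.nan
        terms[name] = TermEstimate(b, se, float(np.exp(b)),
                                   float(np.exp(lo)) if np.isfinite(lo) else np.nan,
                                   float(np.exp(hi)) if np.isfinite(hi) else np.nan,
                                   pval)
        if abs(b) > 8.0 or (np.isfinite(se) and se > 50.0):
            msg = f"possible separation in term {name!r} (beta={b:.2f}, se={se:.2f})"
            fit_warnings.append(msg)
            warnings.warn(msg, SeparationWarning)

    converged = bool(res.success)
    if not converged:
        warnings.warn(f"mixed-logit optimisation did not converge: {res.message}")
    return FitResult(
        design=dataset.design, terms=terms,
        var_subject=float(ss_hat**2), var_trust=float(st_hat**2),
        converged=converged, n_rows=len(y), loglik=loglik, n_quad=n_quad,
        levels=levels, message=str(res.message), warnings=fit_warnings,
    )


def _wald_cov(nll, xhat, active) -> np.ndarray:
    """Inverse observed information on the active set, padded with NaN."""
    k = len(active)
    H = np.empty((k, k))
    steps = np.maximum(1e-4, 1e-4 * np.abs(xhat[active]))
    f0 = nll(xhat)

    def at(offsets):
        x = xhat.copy()
        for idx, d in offsets:
            x[idx] += d
        return nll(x)

    for a in range(k):
        ia, ha = active[a], steps[a]
        H[a, a] = (at([(ia, ha)]) - 2.0 * f0 + at([(ia, -ha)])) / ha**2
        for b in range(a + 1, k):
            ib, hb = active[b], steps[b]
            H[a, b] = H[b, a] = (
                at([(ia, ha), (ib, hb)]) - at([(ia, ha), (ib, -hb)])
                - at([(ia, -ha), (ib, hb)]) + at([(ia, -ha), (ib, -hb)])
            ) / (4.0 * ha * hb)
    try:
        cov_act = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_act = np.linalg.pinv(H)
    cov = np.full((len(xhat), len(xhat)), np.nan)
    for a in range(k):
        for b in range(k):
            cov[active[a], active[b]] = cov_act[a, b]
    return cov


def fit_item_table(panel, design: str, levels: int = 3, adjust: bool = True,
                   items: list[str] | None = None, n_quad: int = 7) -> pd.DataFrame:
    """One separately-fitted adjusted model per item (and per scale total).

    Returns a table with one row per exposure: beta, OR, 95% CI, p, the
    variance components and the convergence flag.  Per-item failures are
    recorded (or/p NaN, error message kept) without aborting the rest.
    """
    from .windows import build_design

    dataset = build_design(panel, design)
    items = items if items is not None else dataset.exposure_columns
    rows = []
    for iid in items:
        rec = {"item_id": iid, "design": design, "levels": levels}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SeparationWarning)
                fr = fit_mixed_logit(dataset, [iid], adjust=adjust, levels=levels, n_quad=n_quad)
            e = fr.terms[iid]
            rec.update(beta=e.beta, se=e.se, odds_ratio=e.or_, ci_lo=e.ci_lo,
                       ci_hi=e.ci_hi, p=e.p, var_subject=fr.var_subject,
                       var_trust=fr.var_trust, converged=fr.converged, error="")
        except Exception as exc:  # keep going; record the failure
            rec.update(beta=np.nan, se=np.nan, odds_ratio=np.nan, ci_lo=np.nan,
                       ci_hi=np.nan, p=np.nan, var_subject=np.nan,
                       var_trust=np.nan, converged=False, error=str(exc))
        rows.append(rec)
    return pd.DataFrame(rows)
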