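"""Nested random-intercept logistic regression: degenerate limits, oracle
agreement with lme4, quadrature stability, and the per-item table workflow."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from proxrisk.cohort import generate_cohort
from proxrisk.config import default_config
from proxrisk.glmm import (
    FitError,
    SeparationWarning,
    _NestedLogitLikelihood,
    build_design_matrix,
    fit_item_table,
    fit_mixed_logit,
)
from proxrisk.windows import build_proximity, build_static


@pytest.fixture(scope="module")
def flat_dataset():
    """No random effects in truth: mixed fit should reduce to plain logistic."""
    cfg = default_config(n_subjects=300, n_trusts=10, sigma_subject=0.0,
                         sigma_trust=0.0, seed=31)
    return build_proximity(generate_cohort(cfg))


@pytest.fixture(scope="module")
def clustered_dataset():
    cfg = default_config(n_subjects=250, n_trusts=12, sigma_subject=1.2,
                         baseline_logit=-2.2, seed=32)
    return build_proximity(generate_cohort(cfg))


class TestDegenerateLimits:
    def test_zero_variance_equals_pooled_logistic(self, flat_dataset):
        fr = fit_mixed_logit(flat_dataset, ["c_violent_ideation"], adjust=True, levels=3)
        X, names, df = build_design_matrix(flat_dataset, ["c_violent_ideation"], True)
        glm = sm.GLM(df["outcome"].to_numpy(), X, family=sm.families.Binomial()).fit()
        for j, name in enumerate(names):
            assert fr.terms[name].beta == pytest.approx(glm.params[j], abs=1e-3)

    def test_three_level_loglik_with_zero_trust_variance_equals_two_level(self, clustered_dataset):
        X, names, df = build_design_matrix(clustered_dataset, ["c_insight"], False)
        y = df["outcome"].to_numpy(dtype=float)
        subj, _ = pd.factorize(df["subject_id"])
        first = np.flatnonzero(np.r_[True, subj[1:] != subj[:-1]])
        trust, _ = pd.factorize(df["trust_id"].to_numpy()[first])
        lik = _NestedLogitLikelihood(X, y, subj, trust)
        beta = np.array([-2.0, 0.8])
        ll2 = lik.loglik(beta, 0.7, 0.0)
        llsub = lik._subject(beta, 0.7, np.zeros(lik.S)).sum()
        assert ll2 == pytest.approx(llsub, abs=1e-12)

    def test_or_equals_exp_beta(self, clustered_dataset):
        fr = fit_mixed_logit(clustered_dataset, ["c_insight"], adjust=False, levels=2)
        e = fr.terms["c_insight"]
        assert e.or_ == pytest.approx(np.exp(e.beta), abs=1e-10)
        assert e.ci_lo <= e.or_ <= e.ci_hi


class TestQuadrature:
    def test_loglik_stabilises_with_node_count(self, clustered_dataset):
        lls, betas = [], []
        for k in (3, 7, 15):
            fr = fit_mixed_logit(clustered_dataset, ["c_violent_ideation"],
                                 adjust=False, levels=2, n_quad=k)
            lls.append(fr.loglik)
            betas.append(fr.terms["c_violent_ideation"].beta)
        # refinement from a coarse rule improves the optimum; past ~7 nodes the
        # approximation error is already below 1e-3 and estimates are stable
        assert lls[1] >= lls[0] - 1e-6
        assert abs(lls[2] - lls[1]) < 1e-3
        assert abs(betas[2] - betas[1]) < 1e-3


class TestOracleLme4:
    def test_two_level_matches_glmer_agq(self, clustered_dataset, tmp_path):
        df = clustered_dataset.data[["subject_id", "outcome", "c_violent_ideation"]]
        csv = tmp_path / "fix.csv"
        df.to_csv(csv, index=False)
        fr = fit_mixed_logit(clustered_dataset, ["c_violent_ideation"],
                             adjust=False, levels=2, n_quad=15)
        rscript = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- glmer(outcome ~ c_violent_ideation + (1|subject_id), data=d,"
            " family=binomial, nAGQ=15);"
            "cat(fixef(m)[2], sqrt(vcov(m)[2,2]), unlist(VarCorr(m)),"
            " as.numeric(logLik(m)), sep=',')"
        )
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True, text=True)
        if out.returncode != 0:
            pytest.skip(f"Rscript/lme4 unavailable: {out.stderr[-200:]}")
        b, se, vs, ll = map(float, out.stdout.strip().split(","))
        e = fr.terms["c_violent_ideation"]
        assert e.beta == pytest.approx(b, abs=2e-3)
        assert e.se == pytest.approx(se, rel=0.02)
        assert fr.var_subject == pytest.approx(vs, abs=0.05)
        assert fr.loglik == pytest.approx(ll, abs=1e-3)


class TestErrorsAndWarnings:
    def test_single_class_outcome_rejected(self, three_subject_panel):
        ds = build_proximity(three_subject_panel)
        ds.data["outcome"] = 0
        with pytest.raises(FitError, match="single class"):
            fit_mixed_logit(ds, ["c_insight"], adjust=False, levels=2)

    def test_constant_exposure_rejected(self, flat_dataset):
        ds = build_proximity(generate_cohort(default_config(n_subjects=50, seed=40)))
        ds.data["flat"] = 1.0
        with pytest.raises(FitError, match="flat"):
            fit_mixed_logit(ds, ["flat"], adjust=False, levels=2)

    def test_separation_warned(self):
        cfg = default_config(n_subjects=80, n_trusts=4, seed=41)
        ds = build_proximity(generate_cohort(cfg))
        ds.data["sep"] = ds.data["outcome"].astype(float)  # perfectly separating exposure
        with pytest.warns(SeparationWarning):
            fit_mixed_logit(ds, ["sep"], adjust=False, levels=2)


class TestItemTable:
    def test_static_table_shape(self, small_panel):
        tab = fit_item_table(small_panel, "static", levels=2, adjust=False)
        h_items = [i for i, d in small_panel.catalogue.items() if d.scale == "H"]
        assert list(tab["item_id"]) == h_items + ["total_h"]
        assert len(tab) == 11

    def test_empty_item_set_gives_empty_table(self, small_panel):
        tab = fit_item_table(small_panel, "proximity", items=[])
        assert len(tab) == 0

    def test_per_item_failure_recorded_not_raised(self, small_panel):
        tab = fit_item_table(small_panel, "proximity", levels=2, adjust=False,
                             items=["c_insight", "no_such_item"])
        assert tab.loc[tab["item_id"] == "no_such_item", "error"].iloc[0] != ""
        assert np.isfinite(tab.loc[tab["item_id"] == "c_insight", "odds_ratio"].iloc[0])

    def test_proximal_ors_larger_under_proximity(self, default_panel):
        items = ["c_violent_ideation", "r_stress_coping"]
        lag = fit_item_table(default_panel, "lagged", levels=2, adjust=False, items=items)
        prox = fit_item_table(default_panel, "proximity", levels=2, adjust=False, items=items)
        assert (prox["odds_ratio"].to_numpy() > lag["odds_ratio"].to_numpy()).all()
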