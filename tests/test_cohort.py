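"""Synthetic cohort generator: calibration, determinism, causal nulls, attrition."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from proxrisk.cohort import EmptyPanelError, generate_cohort, panel_summary
from proxrisk.config import ConfigError, SimConfig, default_config
from proxrisk.items import default_catalogue


def _flat_config(**kw):
    """All causal effects and variance components off."""
    base = dict(rho=0.0, sigma_subject=0.0, sigma_trust=0.0, delta_distal=0.0,
                gamma_proximal={}, baseline_logit=float(logit(0.14)),
                window2_logit_shift=0.0, retention_m6=1.0, retention_m12=1.0)
    base.update(kw)
    return default_config(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value,match", [
        ("ethnicity_probs", (0.5, 0.2, 0.2, 0.2), "ethnicity_probs"),
        ("diagnosis_probs", (0.5, 0.2), "diagnosis_probs"),
        ("rho", 1.0, "rho"),
        ("sigma_subject", -0.1, "sigma_subject"),
        ("p_female", 1.5, "p_female"),
    ])
    def test_invalid_field_named_in_error(self, field, value, match):
        with pytest.raises(ConfigError, match=match):
            default_config(**{field: value})

    def test_threshold_ordering_checked(self):
        th = default_config().item_thresholds.copy()
        th["c_insight"] = (1.0, 1.0)
        with pytest.raises(ConfigError, match="c_insight"):
            default_config(item_thresholds=th)

    def test_gamma_must_point_at_proximal_items(self):
        with pytest.raises(ConfigError, match="c_insight"):
            default_config(gamma_proximal={"c_insight": 1.0})

    def test_yaml_round_trip(self, tmp_path):
        from proxrisk.config import load_config, save_config
        cfg = default_config(seed=99, n_subjects=10)
        save_config(cfg, tmp_path / "cfg.yaml")
        assert load_config(tmp_path / "cfg.yaml") == cfg


class TestGenerateCohort:
    def test_empty_cohort_keeps_full_catalogue(self):
        panel = generate_cohort(default_config(n_subjects=0))
        assert len(panel.data) == 0
        assert set(panel.catalogue) == set(default_catalogue())
        assert all(iid in panel.data.columns for iid in panel.catalogue)

    def test_seed_determinism_byte_identical(self, tmp_path):
        from proxrisk.panel_io import write_panel
        cfg = default_config(n_subjects=60, n_trusts=5, seed=13)
        p1, p2 = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(p1.data, p2.data)
        write_panel(p1, tmp_path / "a.csv")
        write_panel(p2, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_null_prevalence_matches_intercept(self):
        # flat generator, logit(0.14) intercept: both windows ~14% violent
        n = 5000
        panel = generate_cohort(_flat_config(n_subjects=n, seed=5))
        s = panel_summary(panel)
        mc3 = 3 * np.sqrt(0.14 * 0.86 / n)
        for w in ("w1", "w2"):
            assert abs(s["violence"][w]["prevalence"] - 0.14) < mc3

    def test_female_share_calibrated(self):
        n = 5000
        panel = generate_cohort(default_config(n_subjects=n, seed=6))
        s = panel_summary(panel)
        assert abs(s["covariates"]["p_female"] - 0.111) < 3 * np.sqrt(0.111 * 0.889 / n)

    def test_attrition_fractions(self):
        n = 5000
        s = panel_summary(generate_cohort(default_config(n_subjects=n, seed=8)))
        se6 = np.sqrt(0.95 * 0.05 / n)
        assert abs(s["completion"]["m6"]["fraction"] - 0.95) < 4 * se6
        # m12 retention is conditional on m6: marginal expectation 0.95 * 0.89
        se12 = np.sqrt(0.8455 * (1 - 0.8455) / n)
        assert abs(s["completion"]["m12"]["fraction"] - 0.95 * 0.89) < 4 * se12

    def test_full_observation_when_retention_one(self):
        s = panel_summary(generate_cohort(_flat_config(n_subjects=50, seed=1)))
        assert s["completion"]["m6"]["fraction"] == 1.0
        assert s["completion"]["m12"]["fraction"] == 1.0

    def test_historical_items_stable_across_waves(self, default_panel):
        df = default_panel.data
        h_items = [i for i, d in default_panel.catalogue.items() if d.scale == "H"]
        per_subj = df.groupby("subject_id")[h_items].nunique()
        assert (per_subj == 1).all().all()

    def test_violence_only_on_followup_rows(self, default_panel):
        df = default_panel.data
        assert df.loc[df["wave"] == "baseline", "violence_w"].isna().all()
        assert df.loc[df["wave"] != "baseline", "violence_w"].notna().all()


class TestCausalStructure:
    def test_null_wiring_items_independent_of_violence(self):
        # no coupling, no proximal effects: every item's AUC ~ 0.5
        from proxrisk.discrimination import auc_point
        from proxrisk.windows import build_proximity, build_static
        panel = generate_cohort(_flat_config(n_subjects=4000, seed=3))
        ds = build_proximity(panel)
        y = ds.data["outcome"].to_numpy()
        for iid in ("c_violent_ideation", "c_insight", "s_self_control"):
            auc = auc_point(ds.data[iid].to_numpy(), y)
            assert abs(auc - 0.5) < 0.03
        st = build_static(panel)
        auc = auc_point(st.data["h_violence"].to_numpy(), st.data["outcome"].to_numpy())
        assert abs(auc - 0.5) < 0.03

    def test_prevalence_monotone_in_baseline_logit(self):
        prevs = []
        for b0 in (-3.5, -2.0, -0.5):
            s = panel_summary(generate_cohort(default_config(
                n_subjects=3000, baseline_logit=b0, seed=4)))
            prevs.append(s["violence"]["w1"]["prevalence"])
        assert prevs[0] < prevs[1] < prevs[2]

    def test_high_rho_scores_nearly_constant(self):
        panel = generate_cohort(default_config(n_subjects=400, rho=0.999, seed=9))
        df = panel.data
        dyn = [i for i, d in panel.catalogue.items() if d.scale != "H"]
        changed = 0
        total = 0
        for iid in dyn:
            per_subj = df.groupby("subject_id")[iid].nunique()
            changed += int((per_subj > 1).sum())
            total += len(per_subj)
        assert changed / total < 0.05  # latents barely move, so scores barely cross cuts


class TestPanelSummary:
    def test_two_subject_prevalence(self):
        from helpers import make_panel
        panel = make_panel([
            {"subject_id": 1, "trust_id": 1, "waves": {"baseline": {}, "m6": {}, "m12": {}},
             "violence": {"w1": 1, "w2": 0}},
            {"subject_id": 2, "trust_id": 1, "waves": {"baseline": {}, "m6": {}, "m12": {}},
             "violence": {"w1": 0, "w2": 0}},
        ])
        s = panel_summary(panel)
        assert s["violence"]["w1"]["prevalence"] == 0.5
        assert s["violence"]["w2"]["prevalence"] == 0.0
        assert s["completion"]["m12"]["fraction"] == 1.0

    def test_empty_panel_rejected(self):
        with pytest.raises(EmptyPanelError):
            panel_summary(generate_cohort(default_config(n_subjects=0)))
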