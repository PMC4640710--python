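"""Explanatory-variable screening and percentage attenuation of log-odds."""

import numpy as np
import pytest

from proxrisk.attenuation import (
    AttenuationLedger,
    AttenuationRecord,
    UndefinedAttenuationError,
    attenuation_table,
    pct_change,
    screen_explanatory,
)
from proxrisk.cohort import generate_cohort
from proxrisk.config import default_config


class TestPctChange:
    """Worked examples recomputable from published adjusted-odds-ratio pairs."""

    @pytest.mark.parametrize("or_u,or_a,expected", [
        (3.56, 1.59, 63.48),   # risk factor, partial attenuation
        (3.56, 0.99, 100.79),  # adjusted OR crosses 1: change above 100%
        (0.21, 0.65, 72.40),   # protective factor: sign-preserving on the log scale
    ])
    def test_published_worked_examples(self, or_u, or_a, expected):
        assert pct_change(np.log(or_u), np.log(or_a)) == pytest.approx(expected, abs=0.01)

    def test_no_attenuation_is_zero(self):
        assert pct_change(0.7, 0.7) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(UndefinedAttenuationError):
            pct_change(0.0, 0.3)

    def test_reciprocal_or_antisymmetry(self):
        # swapping OR -> 1/OR on both inputs flips both betas' signs: pct unchanged
        rng = np.random.default_rng(3)
        for _ in range(50):
            bu, ba = rng.normal(size=2)
            if bu == 0:
                continue
            assert pct_change(bu, ba) == pytest.approx(pct_change(-bu, -ba))


class TestLedger:
    def test_ledger_recomputes_from_stored_betas(self, small_panel):
        ledgers = attenuation_table(
            small_panel, ["c_insight"], ["c_violent_ideation"],
            levels=2, adjust=False, include_model0=False)
        for led in ledgers.values():
            for r in led.records:
                if np.isfinite(r.pct_change):
                    assert r.pct_change == pct_change(r.beta_unadjusted, r.beta_adjusted)

    def test_empty_explanatory_set_gives_zero_change(self, small_panel):
        ledgers = attenuation_table(small_panel, ["c_insight"], [], levels=2, adjust=False)
        (led,) = ledgers.values()
        assert all(r.pct_change == 0.0 for r in led.records)
        assert all(r.beta_adjusted == r.beta_unadjusted for r in led.records)

    def test_explanatory_set_subset_invariant_enforced(self):
        led = AttenuationLedger("m1", [AttenuationRecord(
            "f", ("x",), 1.0, 0.5, 50.0, 1.6, (1.0, 2.5), 0.1)], ("y",))
        with pytest.raises(ValueError, match="outside"):
            led.validate()


class TestScreen:
    def test_proximal_items_selected_far_more_often_than_distal(self):
        # distal->proximal->violence wiring: the simultaneous screen keeps the
        # proximal drivers most of the time, while distal items can only slip
        # in at the 5% error rate.  The seed band makes the ensemble
        # deterministic, so the frequency contrast is an exact assertion.
        proximal = {"c_violent_ideation", "c_instability", "r_stress_coping"}
        counts: dict[str, int] = {}
        n_seeds = 8
        for seed in range(200, 200 + n_seeds):
            panel = generate_cohort(default_config(seed=seed))
            cands = [i for i, d in panel.catalogue.items() if d.scale in ("C", "R")]
            screened, evidence = screen_explanatory(panel, cands, levels=2, adjust=False)
            assert set(evidence["candidate"]) == set(cands)
            for iid in screened:
                counts[iid] = counts.get(iid, 0) + 1
        distal = [i for i in cands if i not in proximal]
        assert min(counts.get(i, 0) for i in proximal) >= 5
        assert max(counts.get(i, 0) for i in distal) <= 2

    def test_unassociated_candidate_excluded(self):
        # decoupled items (no shared factor, no causal path) fail both legs
        cfg = default_config(item_corr=0.0, delta_distal=0.0, seed=102)
        panel = generate_cohort(cfg)
        screened, evidence = screen_explanatory(
            panel, ["c_insight", "r_living_situation"], levels=2, adjust=False)
        assert "c_insight" not in screened
        assert "r_living_situation" not in screened

    def test_collinear_candidate_passes_marginal_screen(self, small_panel):
        panel = small_panel
        df = panel.data.copy()
        df["c_symptoms"] = df["c_violent_ideation"]  # perfectly collinear pair
        panel2 = type(panel)(df, panel.catalogue, panel.provenance)
        screened, _ = screen_explanatory(
            panel2, ["c_violent_ideation", "c_symptoms"], mode="marginal",
            levels=2, adjust=False)
        assert {"c_violent_ideation", "c_symptoms"} <= set(screened)


def test_model_full_attenuates_distal_factor(default_panel):
    # adding all proximal drivers should push a distal factor's effect toward zero
    ledgers = attenuation_table(
        default_panel, ["c_insight"],
        ["c_violent_ideation", "c_instability", "r_stress_coping"],
        levels=2, adjust=False, include_model0=False)
    full = ledgers["model_full"].records[0]
    assert full.pct_change > 50.0
    assert abs(full.beta_adjusted) < abs(full.beta_unadjusted)
    singles = [ledgers[f"model{k}"].records[0].pct_change for k in (1, 2, 3)]
    assert all(np.isfinite(s) for s in singles)
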