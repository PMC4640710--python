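"""One-command orchestration of the full lagged-vs-proximity analysis.

Stages run in the analysis order: cohort (simulate or read), descriptives,
discrimination (clustered AUC per design), association (per-item multilevel
odds ratios), inter-item correlation summaries, explanatory-variable
screening and attenuation, then comparison figures.  Every table in the
bundle is regenerable from config + seed alone; CSV output uses a fixed
float format so identical runs are byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .attenuation import attenuation_table, screen_explanatory
from .cohort import CohortPanel, generate_cohort, panel_summary
from .config import SimConfig, save_config
from .correlations import spearman_item_summary
from .discrimination import auc_table
from .glmm import fit_item_table
from .items import scale_items, total_score_column
from .panel_io import read_panel, write_panel
from .windows import build_design

__all__ = ["ReportBundle", "run_full_analysis", "render_comparison_figures", "write_bundle"]

_FLOAT_FMT = "%.10g"


@dataclass
class ReportBundle:
    config: SimConfig | None
    seed: int | None
    summary: dict
    auc: dict[str, pd.DataFrame]           # design -> AUC table
    fits: dict[str, pd.DataFrame]          # design -> per-item OR table
    correlations: pd.DataFrame
    screens: dict[str, pd.DataFrame]       # side -> screening evidence
    attenuation: dict[str, pd.DataFrame]   # side -> stacked ledger table
    figures: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        out: dict[str, pd.DataFrame] = {}
        for d, t in self.auc.items():
            out[f"auc_{d}"] = t
        for d, t in self.fits.items():
            out[f"fits_{d}"] = t
        out["correlations"] = self.correlations
        for s, t in self.screens.items():
            out[f"screen_{s}"] = t
        for s, t in self.attenuation.items():
            out[f"attenuation_{s}"] = t
        return out


def run_full_analysis(config: SimConfig | None = None, panel_path=None,
                      panel: CohortPanel | None = None,
                      designs=("lagged", "proximity", "static"),
                      fit_levels: int = 3, adjust: bool = True, n_quad: int = 7,
                      discrimination_items: list[str] | None = None,
                      association_items: list[str] | None = None,
                      run_attenuation: bool = True,
                      risk_candidates: list[str] | None = None,
                      protective_candidates: list[str] | None = None,
                      screen_levels: int | None = None) -> ReportBundle:
    """Run every analysis stage and collect the result tables.

    Exactly one cohort source is used: an in-memory ``panel``, an external
    ``panel_path``, or a simulation from ``config``.  ``*_items`` restrict
    the per-item stages (useful to keep small runs fast); ``None`` means all.
    """
    log: list[str] = []
    t0 = time.perf_counter()

    def stamp(msg: str) -> None:
        log.append(f"[{time.perf_counter() - t0:8.2f}s] {msg}")

    if panel is not None:
        stamp("stage cohort: using in-memory panel")
    elif panel_path is not None:
        panel = read_panel(panel_path)
        stamp(f"stage cohort: read {panel_path} ({panel.n_subjects} subjects)")
    else:
        if config is None:
            raise ValueError("need a config, a panel or a panel_path")
        panel = generate_cohort(config)
        stamp(f"stage cohort: simulated {panel.n_subjects} subjects in {panel.n_trusts} trusts (seed={config.seed})")
    cfg = panel.provenance if isinstance(panel.provenance, SimConfig) else config

    summary = panel_summary(panel)
    prev = summary["violence"]
    stamp(f"stage descriptives: prevalence w1={prev['w1']['prevalence']:.3f} w2={prev['w2']['prevalence']:.3f}")

    datasets = {d: build_design(panel, d) for d in designs}

    auc: dict[str, pd.DataFrame] = {}
    for d, ds in datasets.items():
        items = discrimination_items if (discrimination_items and d != "static") else None
        auc[d] = auc_table(ds, items)
        stamp(f"stage discrimination[{d}]: {len(auc[d])} items, {ds.n_rows} rows")

    fits: dict[str, pd.DataFrame] = {}
    for d in designs:
        items = association_items if (association_items and d != "static") else None
        tab = fit_item_table(panel, d, levels=fit_levels, adjust=adjust, items=items, n_quad=n_quad)
        fits[d] = tab
        n_fail = int((~tab["converged"]).sum()) if len(tab) else 0
        stamp(f"stage association[{d}]: {len(tab)} fits, {n_fail} non-converged")

    corr_rows = []
    for scale in ("H", "C", "R", "SAPROF"):
        for wave in ("baseline", "m6", "m12"):
            if scale == "H" and wave != "baseline":
                continue
            try:
                s = spearman_item_summary(panel, scale, wave)
            except ValueError:
                continue
            corr_rows.append({"scale": scale, "wave": wave, "mean": s.mean, "sd": s.sd,
                              "median": s.median, "n_significant": s.n_significant,
                              "n_pairs": s.n_pairs})
    correlations = pd.DataFrame(corr_rows)
    stamp(f"stage correlations: {len(correlations)} scale x wave summaries")

    screens: dict[str, pd.DataFrame] = {}
    attenuation: dict[str, pd.DataFrame] = {}
    if run_attenuation and "proximity" in designs:
        slv = screen_levels if screen_levels is not None else fit_levels
        sides = {
            "risk": risk_candidates if risk_candidates is not None else (
                scale_items(panel.catalogue, "C") + scale_items(panel.catalogue, "R")),
            "protective": protective_candidates if protective_candidates is not None else
                scale_items(panel.catalogue, "SAPROF"),
        }
        for side, candidates in sides.items():
            candidates = [c for c in candidates if c in panel.data.columns]
            if not candidates:
                continue
            screened, evidence = screen_explanatory(
                panel, candidates, design="proximity", levels=slv, adjust=adjust, n_quad=n_quad)
            screens[side] = evidence
            stamp(f"stage screen[{side}]: selected {screened or 'none'}")
            ptab = fits.get("proximity")
            base = []
            if ptab is not None and len(ptab):
                sig = ptab[(ptab["p"] < 0.05) & ptab["item_id"].isin(candidates)]
                base = [i for i in sig["item_id"] if i not in screened]
            if base and screened:
                ledgers = attenuation_table(panel, base, screened, design="proximity",
                                            levels=fit_levels, adjust=adjust, n_quad=n_quad)
                attenuation[side] = pd.concat([l.to_frame() for l in ledgers.values()],
                                              ignore_index=True)
                stamp(f"stage attenuation[{side}]: {len(base)} base factors x {len(ledgers)} models")
            else:
                attenuation[side] = pd.DataFrame()
                stamp(f"stage attenuation[{side}]: skipped (base={base}, screened={screened})")

    return ReportBundle(config=cfg, seed=cfg.seed if cfg else None, summary=summary,
                        auc=auc, fits=fits, correlations=correlations,
                        screens=screens, attenuation=attenuation, log=log)


def render_comparison_figures(bundle: ReportBundle, out_dir) -> list[str]:
    """Paired lagged-vs-proximity bar charts (white vs grey, 95% CI whiskers).

    Each figure's plotted numbers are also written to a ``*_data.csv`` next to
    it, so the rendering can be audited against the tables it came from.
    A missing design or empty table skips the figure with a log entry.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    made: list[str] = []

    specs = [
        ("auc", bundle.auc, "auc", "AUC", 0.5),
        ("or", bundle.fits, "odds_ratio", "Adjusted odds ratio", 1.0),
    ]
    for tag, tables, value_col, ylabel, refline in specs:
        if not {"lagged", "proximity"} <= set(tables):
            bundle.log.append(f"figure {tag}: skipped (need both lagged and proximity tables)")
            continue
        lag, prox = tables["lagged"], tables["proximity"]
        if len(lag) == 0 or len(prox) == 0:
            bundle.log.append(f"figure {tag}: skipped (empty table)")
            continue
        merged = lag.merge(prox, on="item_id", suffixes=("_lagged", "_proximity"))
        if len(merged) == 0:
            bundle.log.append(f"figure {tag}: skipped (no common items)")
            continue
        data_path = out_dir / f"fig_{tag}_data.csv"
        merged.to_csv(data_path, index=False, float_format=_FLOAT_FMT)

        x = range(len(merged))
        width = 0.38
        fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(merged) + 2), 4))
        for off, dsg, color in ((-width / 2, "lagged", "white"), (width / 2, "proximity", "0.6")):
            v = merged[f"{value_col}_{dsg}"]
            lo = merged[f"ci_lo_{dsg}"]
            hi = merged[f"ci_hi_{dsg}"]
            ax.bar([i + off for i in x], v, width, yerr=[v - lo, hi - v],
                   color=color, edgecolor="black", capsize=2, label=dsg)
        ax.axhline(refline, color="black", lw=0.8, ls=":")
        ax.set_xticks(list(x))
        ax.set_xticklabels(merged["item_id"], rotation=90, fontsize=7)
        ax.set_ylabel(ylabel)
        ax.legend()
        fig.tight_layout()
        fig_path = out_dir / f"fig_{tag}.png"
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
        made += [str(fig_path), str(data_path)]
        bundle.log.append(f"figure {tag}: wrote {fig_path.name}")
    bundle.figures.extend(made)
    return made


def write_bundle(bundle: ReportBundle, out_dir, panel: CohortPanel | None = None,
                 figures: bool = True) -> None:
    """Persist every bundle table (fixed float format), config, log and figures."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, table in bundle.tables().items():
        table.to_csv(out_dir / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
    summ = {k: v for k, v in bundle.summary.items() if k != "item_scores"}
    (out_dir / "summary.json").write_text(json.dumps(summ, indent=1, sort_keys=True))
    bundle.summary["item_scores"].to_csv(out_dir / "item_scores.csv", index=False,
                                         float_format=_FLOAT_FMT)
    if bundle.config is not None:
        save_config(bundle.config, out_dir / "config.yaml")
    if panel is not None:
        write_panel(panel, out_dir / "panel.csv")
    if figures:
        render_comparison_figures(bundle, out_dir)
    (out_dir / "run_log.txt").write_text("\n".join(bundle.log) + "\n")
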