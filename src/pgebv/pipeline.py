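"""End-to-end driver: simulate/ingest -> bin map -> BLUEs -> predict -> report.

Every stage logs its inputs, derived seed and row/column counts; artifact
files are deterministic given the configuration (timestamps live only in
logs).  A stage failure leaves the artifacts written so far plus the
manifest in place.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, binmap as bm, phenostats as ps, prediction as pr
from .simulate import SimConfig, simulate_study

log = logging.getLogger(__name__)


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full pipeline from a config mapping; returns the manifest."""
    out = io.ensure_dir(out_dir)
    sim_cfg = SimConfig.from_dict(config.get("simulation", {}))
    bin_cfg = config.get("binmap", {})
    cv_cfg = config.get("cv", {})
    seed = sim_cfg.seed
    stages: dict = {}

    log.info("stage simulate: %d lines, %d SNPs, seed %d", sim_cfg.n_lines,
             sim_cfg.n_snps, seed)
    clean, noisy, truth, plots = simulate_study(sim_cfg)
    io.write_genotype_csv(noisy, out / "genotypes.csv", out / "marker_map.csv")
    io.write_plot_table(plots, out / "plots.csv")
    io.write_truth(truth, out / "truth.json")
    stages["simulate"] = {"n_lines": clean.n_lines, "n_snps": clean.n_snps,
                          "n_plots": len(plots),
                          "seed": sim_cfg.stage_seed("genotypes")}

    log.info("stage binmap")
    binmap, qc = bm.build_binmap(
        noisy,
        maf_min=bin_cfg.get("maf_min", 0.05),
        missing_max=bin_cfg.get("missing_max", 0.20),
        het_max=bin_cfg.get("het_max", 0.05),
        window=bin_cfg.get("window", 8),
        threshold=bin_cfg.get("threshold", 0.95),
    )
    io.write_binmap(binmap, out / "bins.csv", out / "bin_calls.csv")
    (out / "qc_report.json").write_text(
        pd.Series(qc, dtype=object).to_json(indent=2))
    stages["binmap"] = qc

    log.info("stage blues")
    blues = ps.build_blue_table(plots)
    io.write_blue_table(blues, out / "blues.csv")
    vc = ps.fit_combined_model(plots, "GY")
    h2 = ps.repeatability(vc)
    rep_rows = [{"trait": "GY", "environment": "all", "variant": "across",
                 "h2": h2.h2}]
    for env in dict.fromkeys(plots["env"]):
        r = ps.within_env_repeatability(plots, env, "GY")
        rep_rows.append({"trait": "GY", "environment": env,
                         "variant": "within", "h2": r.h2})
    rep_tab = pd.DataFrame(rep_rows)
    rep_tab.to_csv(out / "repeatability.csv", index=False,
                   float_format=io.FLOAT_FMT)
    vc_payload = pd.Series(vc.as_dict(), dtype=object)
    (out / "variance_components.json").write_text(vc_payload.to_json(indent=2))
    stages["blues"] = {"n_rows": len(blues), "n_traits": blues.shape[1],
                       "n_missing": blues.attrs["n_missing"],
                       "h2_gy": h2.h2}

    log.info("stage predict")
    grid_cfg = pr.GridConfig(
        n_reps=cv_cfg.get("reps", 10),
        n_boot=cv_cfg.get("n_boot", 1000),
        seed=cv_cfg.get("seed", seed),
    )
    for name, params in (cv_cfg.get("learners") or {}).items():
        grid_cfg.learner_specs[name] = pr.LearnerSpec(name, dict(params))
    results = pr.run_experiment_grid(blues, binmap, grid_cfg)
    results.to_csv(out / "results.csv", index=False, float_format=io.FLOAT_FMT)
    summary = pr.summarize_grid(results)
    summary["reps"] = {k: grid_cfg.reps_for(k) for k in grid_cfg.learner_names}
    pd.Series(summary, dtype=object).to_json(out / "summary.json", indent=2)
    stages["predict"] = {"n_cells": summary["n_cells"],
                         "n_failed": summary["n_failed"],
                         "reps": summary["reps"]}

    io.write_manifest(out / "manifest.json", seed, stages)
    return {"seed": seed, "stages": stages, "out_dir": str(out)}


def report(out_dir) -> str:
    """Human-readable summary of a finished run (stdout text)."""
    out = Path(out_dir)
    results = pd.read_csv(out / "results.csv")
    rep = pd.read_csv(out / "repeatability.csv")
    lines = ["prediction accuracy r_GP (rows: learner, columns: input set)"]
    for scheme, grp in results.groupby("scheme"):
        lines.append(f"\n[{scheme}]")
        piv = grp.pivot_table(index="learner", columns="input_set",
                              values="r_gp")
        lines.append(piv.round(3).to_string())
    lines.append("\nrepeatability (GY):")
    lines.append(rep.round(3).to_string(index=False))
    return "\n".join(lines)


def summary_figure(out_dir, path) -> None:
    """Bar chart of the 24-cell grid (schemes x learners x input sets)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = pd.read_csv(Path(out_dir) / "results.csv")
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6), sharey=True)
    for ax, (scheme, grp) in zip(axes, results.groupby("scheme")):
        piv = grp.pivot_table(index="learner", columns="input_set",
                              values="r_gp")
        piv = piv.reindex(index=list(pr.LEARNERS),
                          columns=list(pr.INPUT_SETS))
        x = np.arange(len(piv.index))
        width = 0.25
        for k, c in enumerate(piv.columns):
            ax.bar(x + (k - 1) * width, piv[c], width, label=c)
        ax.set_xticks(x, piv.index)
        ax.set_title(scheme)
        ax.set_ylabel("r_GP")
    axes[0].legend(title="input set", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
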