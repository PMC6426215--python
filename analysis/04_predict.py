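"""Prediction-accuracy grid: {within 2-fold, leave-one-environment-out}
x {PLSR, RF, RR, BayesB} x {M, H, HM}.

Reads the BLUE table and bin map from scratch/pipeline/; writes the tidy
24-cell results table and summary means to results/.  Replications are
desk-scale (10 per learner) by default; pass 'paper' as the second CLI
argument to use the study's per-learner counts (1000/2000/3000/1000).
"""

import sys
from pathlib import Path

import pandas as pd

from pgebv import io
from pgebv import prediction as pr

ROOT = Path(__file__).resolve().parents[1]
WORK = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main(seed: int = 1, reps="10") -> None:
    blues = io.read_blue_table(WORK / "blues.csv")
    binmap = io.read_binmap(WORK / "bins.csv", WORK / "bin_calls.csv")
    cfg = pr.GridConfig(n_reps="paper" if reps == "paper" else int(reps),
                        seed=seed)
    results = pr.run_experiment_grid(blues, binmap, cfg)
    results.to_csv(RESULTS / "04_prediction_grid.csv", index=False,
                   float_format="%.6g")
    summary = pr.summarize_grid(results)

    print("r_GP by cell:")
    for scheme, grp in results.groupby("scheme"):
        print(f"\n[{scheme}]")
        print(grp.pivot_table(index="learner", columns="input_set",
                              values="r_gp").round(3).to_string())
    print("\nmeans: scheme ->", {k: round(v, 3)
                                 for k, v in summary["by_scheme"].items()})
    print("means: learner ->", {k: round(v, 3)
                                for k, v in summary["by_learner"].items()})
    print("means: input set ->", {k: round(v, 3)
                                  for k, v in summary["by_input_set"].items()})
    pd.Series(summary, dtype=object).to_json(
        RESULTS / "04_prediction_summary.json", indent=2)


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    reps = sys.argv[2] if len(sys.argv) > 2 else "10"
    main(seed, reps)
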