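"""Per-environment BLUEs and repeatability.

Fits the alpha-lattice mixed model per environment (genotype fixed, rep
and block random) for grain yield and all 310 band x flight features,
then the all-random across-environment model for variance components and
entry-mean repeatability.

Writes the BLUE table to scratch/pipeline/blues.csv and repeatability /
variance-component summaries to results/.
"""

from pathlib import Path

import pandas as pd

from pgebv import io
from pgebv.phenostats import (build_blue_table, fit_combined_model,
                              repeatability, within_env_repeatability)

ROOT = Path(__file__).resolve().parents[1]
WORK = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main() -> None:
    plots = io.read_plot_table(WORK / "plots.csv")
    blues = build_blue_table(plots)
    io.write_blue_table(blues, WORK / "blues.csv")

    vc = fit_combined_model(plots, "GY")
    h2 = repeatability(vc)
    rows = [{"trait": "GY", "environment": "all", "variant": "across",
             "h2": h2.h2, "sigma_g2": vc.sigma_g2,
             "sigma_gxe2": vc.sigma_gxe2, "sigma_e2": vc.sigma_e2}]
    for env in dict.fromkeys(plots["env"]):
        r = within_env_repeatability(plots, env, "GY")
        rows.append({"trait": "GY", "environment": env, "variant": "within",
                     "h2": r.h2})
    tab = pd.DataFrame(rows)
    tab.to_csv(RESULTS / "03_repeatability.csv", index=False)

    print(f"BLUE table: {blues.shape[0]} genotype x environment rows, "
          f"{blues.shape[1]} traits ({blues.attrs['n_missing']} missing)")
    print("variance components (GY):",
          {k: round(v, 3) for k, v in
           [("sigma_g2", vc.sigma_g2), ("sigma_gxe2", vc.sigma_gxe2),
            ("sigma_e2", vc.sigma_e2)]})
    print(f"entry-mean repeatability h2 = {h2.h2:.3f}; per-environment:")
    print(tab[tab["variant"] == "within"][["environment", "h2"]]
          .round(3).to_string(index=False))


if __name__ == "__main__":
    main()
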