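"""Mixed-model machinery: BLUEs against an explicit-covariance GLS oracle,
REML against lme4, equivariance properties, EM monotonicity and
repeatability formulas."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from pgebv import phenostats as ph
from pgebv.simulate import SimConfig, default_map, simulate_dh_genotypes, \
    assign_qtl_effects, simulate_trials


def _toy_plots(seed, n_geno=12, sigma_rep2=0.3, sigma_block2=0.2,
               sigma_e2=1.0, block_size=4):
    """One environment, 2 reps, incomplete blocks of 4, known components."""
    rng = np.random.default_rng(seed)
    genos = [f"G{i}" for i in range(n_geno)]
    gvals = rng.normal(0, 1, n_geno)
    rows = []
    for rep in (1, 2):
        rep_eff = rng.normal(0, np.sqrt(sigma_rep2))
        perm = rng.permutation(n_geno)
        n_blocks = n_geno // block_size
        beff = rng.normal(0, np.sqrt(sigma_block2), n_blocks)
        for slot, gi in enumerate(perm):
            b = slot // block_size
            rows.append({"env": "E1", "rep": rep,
                         "block": f"E1_R{rep}_B{b}", "genotype": genos[gi],
                         "GY": 5 + gvals[gi] + rep_eff + beff[b]
                         + rng.normal(0, np.sqrt(sigma_e2))})
    return pd.DataFrame(rows), pd.Series(gvals, index=genos)


def _gls_oracle(plots, sigma_rep2, sigma_block2, sigma_e2):
    """BLUEs by explicit-covariance GLS at the true components."""
    genos = sorted(plots["genotype"].unique())
    X = pd.get_dummies(plots["genotype"]).reindex(columns=genos).to_numpy(float)
    Zr = pd.get_dummies(plots["rep"]).to_numpy(float)
    Zb = pd.get_dummies(plots["block"]).to_numpy(float)
    V = (sigma_rep2 * Zr @ Zr.T + sigma_block2 * Zb @ Zb.T
         + sigma_e2 * np.eye(len(plots)))
    Vi = np.linalg.inv(V)
    y = plots["GY"].to_numpy()
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return pd.Series(beta, index=genos)


class TestEnvModel:
    def test_collapses_to_genotype_means_without_rep_block_variance(self):
        plots, _ = _toy_plots(seed=1, sigma_rep2=0.0, sigma_block2=0.0)
        blues, vc, _ = ph.fit_env_model(plots, "E1", "GY")
        means = plots.groupby("genotype")["GY"].mean()
        # rep/block variances estimated ~0 -> GLS ~ OLS = plain means
        assert np.allclose(blues, means.loc[blues.index], atol=5e-2)

    def test_translation_equivariance(self):
        plots, _ = _toy_plots(seed=2)
        b1, vc1, _ = ph.fit_env_model(plots, "E1", "GY")
        shifted = plots.copy()
        shifted["GY"] += 7.5
        b2, vc2, _ = ph.fit_env_model(shifted, "E1", "GY")
        assert np.allclose(b2 - b1, 7.5, atol=1e-6)
        assert vc2.sigma_e2 == pytest.approx(vc1.sigma_e2, rel=1e-4)

    def test_gls_at_true_covariance_matches_explicit_oracle(self):
        """The MME solver at the true components equals dense-V GLS."""
        for seed in range(10):
            plots, _ = _toy_plots(seed=seed)
            oracle = _gls_oracle(plots, 0.3, 0.2, 1.0)
            X, genos = ph._indicator(plots["genotype"])
            Zr, _ = ph._indicator(plots["rep"])
            Zb, _ = ph._indicator(plots["block"])
            beta = ph.gls_solve(plots["GY"].to_numpy(), X,
                                {"rep": Zr, "block": Zb},
                                {"rep": 0.3, "block": 0.2, "e": 1.0})
            assert np.allclose(beta, oracle.loc[genos], atol=1e-8)

    def test_reml_blues_unbiased_against_gls_oracle(self):
        """Across seeds, REML-based BLUEs are centered on the
        true-covariance GLS oracle (the per-seed spread is REML noise on
        a 2-rep / 6-block toy)."""
        diffs = []
        for seed in range(200):
            plots, _ = _toy_plots(seed=seed)
            blues, _, _ = ph.fit_env_model(plots, "E1", "GY")
            oracle = _gls_oracle(plots, 0.3, 0.2, 1.0)
            diffs.append((blues - oracle.loc[blues.index]).to_numpy())
        bias = np.mean(diffs, axis=0)
        assert np.sqrt(np.mean(bias ** 2)) < 0.05

    def test_absent_genotype_flagged_missing(self):
        plots, _ = _toy_plots(seed=3)
        plots = plots[plots["genotype"] != "G5"]
        extra = pd.DataFrame([{"env": "E1", "rep": 1, "block": "E1_R1_B0",
                               "genotype": "G5", "GY": np.nan}])
        plots = pd.concat([plots, extra], ignore_index=True)
        blues, _, _ = ph.fit_env_model(plots, "E1", "GY")
        assert np.isnan(blues.loc["G5"])
        assert blues.drop("G5").notna().all()


class TestCombinedModel:
    def test_scale_equivariance(self, mini_study):
        _, _, _, plots = mini_study
        vc1 = ph.fit_combined_model(plots, "GY")
        doubled = plots.copy()
        doubled["GY"] *= 2
        vc2 = ph.fit_combined_model(doubled, "GY")
        assert vc2.sigma_g2 == pytest.approx(4 * vc1.sigma_g2, rel=1e-3)
        assert vc2.sigma_e2 == pytest.approx(4 * vc1.sigma_e2, rel=1e-3)

    def test_null_gxe_estimated_near_zero(self):
        """Median GxE estimate under a zero-GxE simulation is ~0."""
        spec = default_map(n_snps=40)
        est = []
        for seed in range(30):
            cfg = SimConfig(n_snps=40, gxe_ratio=0.0, seed=3000 + seed)
            g = simulate_dh_genotypes(spec, 97, cfg.stage_seed("genotypes"))
            truth = assign_qtl_effects(g, 5, 1.0, cfg.stage_seed("qtl"))
            plots = simulate_trials(truth, cfg)
            est.append(ph.fit_combined_model(plots, "GY").sigma_gxe2)
        assert np.median(est) < 0.05

    def test_matches_lme4_reference(self, mini_study, tmp_path):
        """Independent oracle: lme4 REML on the same data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        _, _, _, plots = mini_study
        sub = plots[["env", "rep", "block", "genotype", "GY"]].copy()
        csv = tmp_path / "plots.csv"
        sub.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{csv}")\n'
            'd$rep_env <- paste0(d$env, "_R", d$rep)\n'
            'm <- lmer(GY ~ 1 + (1|genotype) + (1|env) + (1|env:genotype) + '
            '(1|rep_env) + (1|block), data=d, REML=TRUE, '
            'control=lmerControl(check.conv.singular="ignore"))\n'
            'vc <- as.data.frame(VarCorr(m))\n'
            f'write.csv(vc[,c("grp","vcov")], "{tmp_path}/vc.csv", '
            'row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "vc.csv").set_index("grp")["vcov"]
        vc = ph.fit_combined_model(plots, "GY")
        vy = plots["GY"].var()
        assert vc.sigma_g2 == pytest.approx(ref["genotype"], abs=0.01 * vy)
        assert vc.sigma_gxe2 == pytest.approx(ref["env:genotype"],
                                              abs=0.01 * vy)
        assert vc.sigma_e2 == pytest.approx(ref["Residual"], abs=0.01 * vy)


class TestRemlInternals:
    def test_em_objective_monotone_on_toy(self):
        plots, _ = _toy_plots(seed=4)
        y = plots["GY"].to_numpy()
        X, _ = ph._indicator(plots["genotype"])
        Zr, _ = ph._indicator(plots["rep"])
        Zb, _ = ph._indicator(plots["block"])
        fit = ph.reml_em(y, X, {"rep": Zr, "block": Zb}, method="em",
                         accelerate=False, track=True, max_iter=200)
        assert fit.history is not None
        assert np.all(np.diff(fit.history) <= 1e-8)

    def test_restricted_ll_matches_direct_formula(self):
        """MME-based -2 loglik identity against the dense-V computation."""
        plots, _ = _toy_plots(seed=5)
        y = plots["GY"].to_numpy()
        X, _ = ph._indicator(plots["genotype"])
        Zr, _ = ph._indicator(plots["rep"])
        Zb, _ = ph._indicator(plots["block"])
        fit = ph.reml_em(y, X, {"rep": Zr, "block": Zb})
        s = {k: max(v, 1e-8) for k, v in fit.sigma2.items()}
        V = (s["rep"] * Zr @ Zr.T + s["block"] * Zb @ Zb.T
             + s["e"] * np.eye(len(y)))
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        resid = y - X @ beta
        direct = (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1]
                  + float(resid @ Vi @ resid))
        assert -2 * fit.loglik == pytest.approx(direct, abs=1e-6)

    def test_nonnegative_components_truncated(self):
        plots, _ = _toy_plots(seed=6, sigma_rep2=0.0, sigma_block2=0.0)
        _, vc, _ = ph.fit_env_model(plots, "E1", "GY")
        assert vc.sigma_rep2 >= 0 and vc.sigma_block2 >= 0


class TestRepeatability:
    def test_perfect_heritability(self):
        vc = ph.VarianceComponents(sigma_g2=1, sigma_gxe2=0, sigma_e2=0,
                                   n_envs=4, n_reps=2)
        assert ph.repeatability(vc).h2 == pytest.approx(1.0)

    def test_interpreted_formula_value(self):
        vc = ph.VarianceComponents(sigma_g2=2, sigma_gxe2=2, sigma_e2=4,
                                   n_envs=4, n_reps=2)
        assert ph.repeatability(vc).h2 == pytest.approx(2 / 3)

    def test_zero_denominator_flagged(self):
        vc = ph.VarianceComponents(sigma_g2=0, sigma_gxe2=0, sigma_e2=0,
                                   n_envs=4, n_reps=2)
        assert np.isnan(ph.repeatability(vc).h2)

    def test_within_variant_classical_formula(self):
        vc = ph.VarianceComponents(sigma_g2=1, sigma_gxe2=0.5, sigma_e2=2,
                                   n_envs=1, n_reps=2)
        assert ph.repeatability(vc, variant="within").h2 == \
            pytest.approx(1 / (1 + 1))


class TestBlueTable:
    def test_dimensions(self, mini_study, mini_blues, mini_config):
        _, _, _, plots = mini_study
        n_features = mini_config.n_bands * mini_config.n_flights
        assert mini_blues.shape == (97 * 4, 1 + n_features)
        assert mini_blues.index.names == ["genotype", "env"]

    def test_environment_without_reflectance(self, mini_study):
        _, _, _, plots = mini_study
        band_cols = ph.band_columns(plots)
        broken = plots.copy()
        broken.loc[broken["env"] == "16DS", band_cols] = np.nan
        blues = ph.build_blue_table(broken, traits=["GY", band_cols[0]])
        sub = blues.xs("16DS", level="env")
        assert sub[band_cols[0]].isna().all()
        assert sub["GY"].notna().all()

    def test_gy_blues_track_truth_in_clean_setting(self, clean_geno):
        cfg = SimConfig(n_snps=1000, sigma_rep2=0.0, sigma_block2=0.0,
                        sigma_e2=1e-4, seed=12)
        truth = assign_qtl_effects(clean_geno, 5, 1.0, seed=12)
        plots = simulate_trials(truth, cfg)
        blues = ph.build_blue_table(plots, traits=["GY"])
        gvals = pd.Series(truth.genetic_values, index=truth.line_ids)
        gxe = pd.DataFrame(truth.gxe_values, index=truth.line_ids,
                           columns=truth.env_ids)
        for j, env in enumerate(truth.env_ids):
            sub = blues.xs(env, level="env")["GY"]
            target = gvals.loc[sub.index] + gxe.loc[sub.index, env]
            assert np.corrcoef(sub, target)[0, 1] > 0.9999
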