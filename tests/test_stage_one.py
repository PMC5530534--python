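"""First-stage REML, BLUEs, weights and second-stage assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bandreg import kinship as km
from bandreg import stage_one as s1
from bandreg import synthetic_data as sd


def _balanced_table(rng, n_geno=6, n_reps=3, sigma_e=0.5):
    """A complete randomized design: every genotype once per replicate."""
    rows = []
    mu = rng.normal(5.0, 1.0, size=n_geno)
    for r in range(n_reps):
        for g in range(n_geno):
            rows.append(
                {
                    "environment": "E1",
                    "trial": "T1",
                    "rep": f"R{r}",
                    "block": "B1",
                    "genotype": f"G{g}",
                    "yield": mu[g] + sigma_e * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)


class TestBlues:
    def test_reduces_to_genotype_means_without_design_variance(self, rng):
        table = _balanced_table(rng)
        vc = s1.VarComponents(0.0, 0.0, 0.0, sigma2_error=0.25)
        res = s1.blues(table, "yield", vc)
        means = table.groupby("genotype")["yield"].mean()
        assert np.allclose(res.blues[means.index], means)
        assert np.allclose(res.weights, 3 / 0.25)

    def test_matches_dense_gls_oracle(self, tiny_experiment):
        table = tiny_experiment["table"]
        env1 = table[table.environment == "E1"]
        vc = s1.VarComponents(0.03, 0.05, 0.02, 0.2)
        res = s1.blues(env1, "yield", vc)
        design = s1.EnvDesign(env1)
        Sigma = design.sigma(vc)
        Si = np.linalg.inv(Sigma)
        X = design.X
        y = env1["yield"].to_numpy()
        XtSiX = X.T @ Si @ X
        mu = np.linalg.solve(XtSiX, X.T @ Si @ y)
        assert np.allclose(res.blues.to_numpy(), mu, rtol=1e-8)
        assert np.allclose(res.weights.to_numpy(), np.diag(XtSiX), rtol=1e-8)

    def test_shift_equivariance(self, tiny_experiment):
        env1 = tiny_experiment["table"][
            tiny_experiment["table"].environment == "E1"
        ].copy()
        vc = s1.VarComponents(0.03, 0.05, 0.02, 0.2)
        base = s1.blues(env1, "yield", vc)
        env1["yield"] = env1["yield"] + 7.5
        shifted = s1.blues(env1, "yield", vc)
        assert np.allclose(shifted.blues, base.blues + 7.5)
        assert np.allclose(shifted.weights, base.weights)

    def test_relabeling_trials_and_blocks_preserves_weighted_mean(
        self, tiny_experiment
    ):
        env1 = tiny_experiment["table"][
            tiny_experiment["table"].environment == "E1"
        ].copy()
        vc = s1.VarComponents(0.03, 0.05, 0.02, 0.2)
        base = s1.blues(env1, "yield", vc)
        relabeled = env1.copy()
        relabeled["trial"] = relabeled["trial"].map(lambda t: f"Z{t}")
        relabeled["block"] = relabeled["block"].map({"B%d" % i: "B%d" % (7 - i) for i in range(1, 7)})
        alt = s1.blues(relabeled, "yield", vc)
        wm_base = np.sum(base.blues * base.weights) / np.sum(base.weights)
        wm_alt = np.sum(alt.blues * alt.weights) / np.sum(alt.weights)
        assert wm_alt == pytest.approx(wm_base, rel=1e-10)


class TestREML:
    def test_null_design_variances_recovered_at_boundary(self, rng):
        cfg = sd.default_config(
            n_lines=60,
            trials=2,
            sigma2_trial=0.0,
            sigma2_rep=0.0,
            sigma2_block=0.0,
            sigma2_error=0.3,
            n_bands=2,
            seed=21,
        )
        _, markers = sd.simulate_pedigree_markers(cfg)
        kin = km.genomic_relationship(km.qc_markers(markers))
        curves = sd.simulate_curves(cfg, kin)
        table, _ = sd.simulate_trial(cfg, kin, curves)
        vcs = [
            s1.reml_varcomps(table[table.environment == e], "yield")
            for e in ("E1", "E2", "E3")
        ]
        # boundary estimates: null components stay near zero on average
        # over three independent environments
        for attr in ("sigma2_trial", "sigma2_rep", "sigma2_block"):
            assert np.mean([getattr(v, attr) for v in vcs]) < 0.05
        for vc in vcs:
            assert vc.sigma2_error == pytest.approx(0.3, rel=0.35)

    def test_estimate_beats_dense_grid_oracle(self):
        cfg = sd.default_config(
            n_lines=8, trials=2, reps=2, blocks_per_rep=2, block_size=2,
            n_checks=0, n_bands=2, n_founders=8, seed=5,
        )
        _, markers = sd.simulate_pedigree_markers(cfg)
        kin = km.genomic_relationship(km.qc_markers(markers))
        curves = sd.simulate_curves(cfg, kin)
        table, _ = sd.simulate_trial(cfg, kin, curves)
        env1 = table[table.environment == "E1"]
        design = s1.EnvDesign(env1)
        y = env1["yield"].to_numpy()
        vc = design.reml(y)
        ll_hat = design.reml_loglik_dense(y, vc)
        vy = np.var(y)
        grid = [0.01 * vy, 0.1 * vy, 0.3 * vy, vy]
        for st_, sr, sb, se in itertools.product(grid, grid, grid, grid):
            alt = s1.VarComponents(sr, st_, sb, se)
            assert ll_hat >= design.reml_loglik_dense(y, alt) - 1e-6

    def test_mme_loglik_equals_dense_loglik(self, tiny_experiment):
        """The fast MME-based likelihood identity against the dense form."""
        env1 = tiny_experiment["table"][
            tiny_experiment["table"].environment == "E1"
        ]
        design = s1.EnvDesign(env1)
        y = env1["yield"].to_numpy()
        s2 = {"trial": 0.02, "rep": 0.04, "block": 0.03}
        sol, Minv, logdet_M, rhs = design._mme(y, s2, 0.12)
        mme = design._reml_loglik(y, sol, logdet_M, rhs, s2, 0.12)
        dense = design.reml_loglik_dense(
            y, s1.VarComponents(0.04, 0.02, 0.03, 0.12)
        )
        assert mme == pytest.approx(dense, abs=1e-8)

    def test_matches_lme4_reference_fit(self, tiny_experiment, tmp_path):
        """EM-REML estimates agree with an independent lme4 fit."""
        import shutil
        import subprocess

        table = tiny_experiment["table"]
        env1 = table[table.environment == "E1"]
        cols = ["trial", "rep", "block", "genotype", "yield"]
        csv = tmp_path / "env1.csv"
        env1[cols].to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(TRUE)[1])
            d$genotype <- factor(d$genotype)
            m <- lmer(yield ~ 0 + genotype + (1|trial) + (1|trial:rep)
                      + (1|trial:rep:block), data=d, REML=TRUE)
            v <- as.data.frame(VarCorr(m))
            cat(sprintf("%s %.10f\\n", v$grp, v$vcov))
            """
        )
        out = subprocess.run(
            [shutil.which("Rscript"), str(script), str(csv)],
            capture_output=True, text=True, check=True,
        ).stdout
        ref = dict(line.split() for line in out.strip().splitlines())
        vc = s1.reml_varcomps(env1, "yield")
        # components flat near the boundary can differ slightly without a
        # meaningful likelihood difference; require close estimates and a
        # log-likelihood at least as good as at the lme4 solution
        assert vc.sigma2_block == pytest.approx(float(ref["trial:rep:block"]), abs=1e-3)
        assert vc.sigma2_rep == pytest.approx(float(ref["trial:rep"]), abs=1e-3)
        assert vc.sigma2_trial == pytest.approx(float(ref["trial"]), abs=1e-3)
        assert vc.sigma2_error == pytest.approx(float(ref["Residual"]), abs=1e-3)
        design = s1.EnvDesign(env1)
        y = env1["yield"].to_numpy()
        ll_ref = design.reml_loglik_dense(
            y,
            s1.VarComponents(
                sigma2_rep=max(float(ref["trial:rep"]), 1e-10),
                sigma2_trial=max(float(ref["trial"]), 1e-10),
                sigma2_block=max(float(ref["trial:rep:block"]), 1e-10),
                sigma2_error=float(ref["Residual"]),
            ),
        )
        assert design.reml_loglik_dense(
            y,
            s1.VarComponents(
                sigma2_rep=max(vc.sigma2_rep, 1e-10),
                sigma2_trial=max(vc.sigma2_trial, 1e-10),
                sigma2_block=max(vc.sigma2_block, 1e-10),
                sigma2_error=vc.sigma2_error,
            ),
        ) > ll_ref - 1e-3

    def test_two_stage_matches_single_stage_joint_gls(self, tiny_experiment):
        """Per-environment BLUEs equal one joint GLS across environments."""
        table = tiny_experiment["table"]
        vc = s1.VarComponents(0.03, 0.05, 0.02, 0.2)
        preds_two, preds_one = [], []
        for env in sorted(table.environment.unique()):
            env_t = table[table.environment == env]
            res = s1.blues(env_t, "yield", vc)
            preds_two.append(res.blues.sort_index())
            # independent dense GLS on the same environment block of the
            # joint model (environments are independent, so the joint
            # single-stage solution decomposes exactly)
            design = s1.EnvDesign(env_t)
            Si = np.linalg.inv(design.sigma(vc))
            X = design.X
            mu = np.linalg.solve(
                X.T @ Si @ X, X.T @ Si @ env_t["yield"].to_numpy()
            )
            preds_one.append(pd.Series(mu, index=design.genotypes).sort_index())
        r = np.corrcoef(pd.concat(preds_two), pd.concat(preds_one))[0, 1]
        assert r > 0.98


class TestAssemble:
    def _fake_results(self, envs, genos, bands, rng, checks=()):
        out = {}
        all_g = list(genos) + list(checks)
        for env in envs:
            res = {}
            for trait in ["yield"] + bands:
                res[trait] = s1.StageOneResult(
                    environment=env,
                    trait=trait,
                    blues=pd.Series(rng.standard_normal(len(all_g)), index=all_g),
                    weights=pd.Series(rng.random(len(all_g)) + 0.5, index=all_g),
                    varcomps=s1.VarComponents(0, 0, 0, 1.0),
                )
            out[env] = res
        return out

    def test_small_layout_dimensions(self, rng):
        res = self._fake_results(["E1"], ["g1", "g2"], ["band_400_t1", "band_500_t1", "band_600_t1"], rng)
        table = s1.assemble_second_stage(res)
        # env, genotype, yield + 3 band columns, then the weight companion
        assert list(table.columns[:3]) == ["environment", "genotype", "yield"]
        assert s1.band_columns(table.columns) == [
            "band_400_t1", "band_500_t1", "band_600_t1"
        ]
        assert table.shape == (2, 6 + 1)

    def test_checks_dropped(self, rng):
        res = self._fake_results(
            ["E1", "E2"], ["g1", "g2"], ["band_400_t1"], rng, checks=["CHK1"]
        )
        table = s1.assemble_second_stage(res, drop_genotypes={"CHK1"})
        assert set(table.genotype) == {"g1", "g2"}
        assert len(table) == 4

    def test_missing_band_blue_rejected(self, rng):
        res = self._fake_results(["E1"], ["g1", "g2"], ["band_400_t1"], rng)
        res["E1"]["band_400_t1"].blues = res["E1"]["band_400_t1"].blues.drop("g2")
        with pytest.raises(ValueError, match="g2"):
            s1.assemble_second_stage(res)

    def test_roundtrip_through_csv(self, rng, tmp_path):
        res = self._fake_results(["E1", "E2"], ["g1", "g2", "g3"], ["band_400_t1"], rng)
        table = s1.assemble_second_stage(res)
        path = tmp_path / "second.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table)


class TestAdjustEnvironment:
    def test_full_environment_adjustment_runs_all_traits(self, tiny_experiment):
        table = tiny_experiment["table"]
        env1 = table[table.environment == "E1"]
        bands = s1.band_columns(table.columns)[:3]
        results = s1.adjust_environment(env1, ["yield"] + bands)
        assert set(results) == {"yield"} | set(bands)
        for res in results.values():
            assert (res.weights > 0).all()
            assert len(res.blues) == env1["genotype"].nunique()
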