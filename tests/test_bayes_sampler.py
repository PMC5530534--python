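"""Gibbs sampler correctness: conjugate checks, closed-form oracles,
reproducibility and the pinned residual variance."""

import numpy as np
import pandas as pd
import pytest

from bandreg import bayes_sampler as bs
from bandreg import kinship as km
from bandreg import model_catalog as mc
from bandreg.model_catalog import DesignBlock, DesignBundle


def _cells(n):
    return pd.DataFrame(
        {"environment": ["E1"] * n, "genotype": [f"L{i}" for i in range(n)]}
    )


def _bundle(y, blocks, n_envs=1):
    n = len(y)
    return DesignBundle(
        y=np.asarray(y, float),
        blocks=blocks,
        cells=_cells(n),
        envs=[f"E{i+1}" for i in range(n_envs)],
        spec=mc.ModelSpec("M1", "WO"),
    )


class TestConjugateChecks:
    def test_intercept_posterior_matches_sample_mean(self, rng):
        n = 200
        y = 3.0 + rng.standard_normal(n)
        bundle = _bundle(y, [DesignBlock("mu", np.ones((n, 1)), "fixed")])
        fit = bs.gibbs_fit(bundle, bs.SamplerConfig(2000, 1000, seed=1))
        # residual pinned at 1: posterior is N(ybar·n/(n+1e-4), ~1/n)
        assert fit.coef_mean[0] == pytest.approx(
            y.mean(), abs=3 * max(fit.coef_sd[0], 1 / np.sqrt(n))
        )

    def test_variance_chain_matches_analytic_scaled_inv_chi2(self, rng):
        """With coefficients pinned by a near-deterministic likelihood, the
        block-variance chain is an exact scaled-inv-chi-square draw."""
        k, c = 12, 1e6
        beta_true = rng.standard_normal(k)
        y = np.sqrt(c) * beta_true  # noiseless up to the pinned unit residual
        X = np.sqrt(c) * np.eye(k)
        bundle = _bundle(y, [DesignBlock("b", X, "random")])
        S0, df0 = 3.0, 9.0
        priors = bs.PriorConfig(block_scale={"b": S0}, block_df={"b": df0})
        fit = bs.gibbs_fit(
            bundle, bs.SamplerConfig(22_000, 2_000, seed=4), priors=priors
        )
        chain = fit.variance_chains["b"]
        ss = float(beta_true @ beta_true)
        post_scale, post_df = S0 + ss, df0 + k
        exp_mean = post_scale / (post_df - 2)
        exp_var = 2 * post_scale**2 / ((post_df - 2) ** 2 * (post_df - 4))
        se_mean = np.sqrt(exp_var / 2000)  # generous effective sample size
        assert chain.mean() == pytest.approx(exp_mean, abs=5 * se_mean)
        assert chain.var() == pytest.approx(exp_var, rel=0.25)

    def test_prior_invariance_under_joint_resampling(self, rng):
        """Geweke-style successive substitution: alternating draws of data
        given parameters and parameters given data leave the prior invariant
        on a two-parameter conjugate toy (mean + residual variance)."""
        v0, S0, df0, n = 4.0, 2.0, 8.0, 5
        mu, s2 = 0.0, S0 / (df0 - 2)
        mus, s2s = [], []
        for _ in range(40_000):
            y = mu + np.sqrt(s2) * rng.standard_normal(n)
            prec = n / s2 + 1 / v0
            mu = y.sum() / s2 / prec + rng.standard_normal() / np.sqrt(prec)
            resid = y - mu
            s2 = bs.sample_scaled_inv_chi2(rng, S0 + resid @ resid, df0 + n)
            mus.append(mu)
            s2s.append(s2)
        mus, s2s = np.array(mus[2000:]), np.array(s2s[2000:])
        assert mus.mean() == pytest.approx(0.0, abs=0.15)
        assert mus.var() == pytest.approx(v0, rel=0.15)
        assert s2s.mean() == pytest.approx(S0 / (df0 - 2), rel=0.15)


class TestClosedFormOracle:
    def test_fixed_variances_match_mixed_model_equations(self, rng):
        """With every variance pinned, posterior coefficient means equal
        the closed-form joint ridge/GLS solution."""
        t, lines = _make_table(rng)
        kin = km.identity_kinship(lines)
        bundle = mc.compile(mc.ModelSpec("M4", "WG"), t, kinships={"G": kin})
        fixed = {"g": 0.5, "gE": 0.3, "bands": 0.05}
        big = 1e9
        priors = bs.PriorConfig(
            block_scale={k: v * (big + 2) for k, v in fixed.items()},
            block_df={k: big for k in fixed},
        )
        fit = bs.gibbs_fit(
            bundle, bs.SamplerConfig(30_000, 5_000, seed=2), priors=priors
        )
        X = bundle.design_matrix()
        prior_prec = np.concatenate(
            [
                np.full(b.X.shape[1], 1.0 / (1e4 if b.prior == "fixed" else fixed[b.name]))
                for b in bundle.blocks
            ]
        )
        A = X.T @ X + np.diag(prior_prec)  # residual pinned at 1
        expected = np.linalg.solve(A, X.T @ bundle.y)
        scale = np.abs(expected).max()
        assert np.abs(fit.coef_mean - expected).max() < 0.01 * scale


def _make_table(rng, n_lines=12, p=16):
    lines = [f"L{i}" for i in range(n_lines)]
    rows = []
    for e in ["E1", "E2", "E3"]:
        for l in lines:
            rows.append({"environment": e, "genotype": l, "yield": rng.normal(5, 1)})
    t = pd.DataFrame(rows)
    wl = np.linspace(400, 800, p)
    bands = 0.3 + 0.05 * rng.standard_normal((len(t), p))
    t = pd.concat(
        [t, pd.DataFrame(bands, columns=[f"band_{w:.0f}_t1" for w in wl])], axis=1
    )
    return t, lines


class TestSamplerContracts:
    def test_seeded_runs_bit_reproducible(self, rng):
        t, lines = _make_table(rng)
        bundle = mc.compile(mc.ModelSpec("M4", "WO", L=7, S=7), t)
        cfg = bs.SamplerConfig(500, 100, seed=11)
        f1 = bs.gibbs_fit(bundle, cfg)
        f2 = bs.gibbs_fit(bundle, cfg)
        assert np.array_equal(f1.coef_mean, f2.coef_mean)
        assert np.array_equal(
            f1.variance_chains["residual"], f2.variance_chains["residual"]
        )

    def test_residual_chain_pinned_near_one(self, rng):
        t, lines = _make_table(rng)
        bundle = mc.compile(mc.ModelSpec("M2", "WO"), t)
        fit = bs.gibbs_fit(bundle, bs.SamplerConfig(2000, 500, seed=3))
        chain = fit.variance_chains["residual"]
        inside = np.mean((chain > 0.9) & (chain < 1.1))
        assert inside >= 0.99

    def test_posterior_means_invariant_to_row_permutation(self, rng):
        t, lines = _make_table(rng)
        bundle = mc.compile(mc.ModelSpec("M3", "WO", L=7, S=7), t)
        perm = rng.permutation(len(t))
        bundle_p = mc.compile(
            mc.ModelSpec("M3", "WO", L=7, S=7), t.iloc[perm].reset_index(drop=True)
        )
        f1 = bs.gibbs_fit(bundle, bs.SamplerConfig(6000, 2000, seed=5))
        f2 = bs.gibbs_fit(bundle_p, bs.SamplerConfig(6000, 2000, seed=6))
        sd = np.maximum(np.maximum(f1.coef_sd, f2.coef_sd), 1e-3)
        frac_close = np.mean(np.abs(f1.coef_mean - f2.coef_mean) < 4 * sd)
        assert frac_close > 0.95

    def test_non_finite_response_rejected(self, rng):
        y = np.array([1.0, np.nan, 2.0])
        bundle = _bundle(y, [DesignBlock("mu", np.ones((3, 1)), "fixed")])
        with pytest.raises(ValueError, match="non-finite"):
            bs.gibbs_fit(bundle, bs.SamplerConfig(10, 1, seed=0))


class TestPredict:
    def test_training_row_prediction_close_to_response(self, rng):
        """On nearly noiseless data the fit reproduces training responses."""
        n = 60
        lines = [f"L{i}" for i in range(n)]
        g_true = rng.standard_normal(n)
        y = 5.0 + g_true
        blocks = [
            DesignBlock("env", np.ones((n, 1)), "fixed"),
            DesignBlock("g", np.eye(n), "random"),
        ]
        bundle = _bundle(y, blocks)
        fit = bs.gibbs_fit(bundle, bs.SamplerConfig(4000, 1000, seed=7))
        pred = bs.predict(fit)
        assert np.corrcoef(pred, y)[0, 1] > 0.95

    def test_wo_unseen_line_contribution_is_zero(self, rng):
        t, lines = _make_table(rng)
        bundle = mc.compile(mc.ModelSpec("M1", "WO"), t)
        unseen = t.genotype == "L0"
        train = np.where(~unseen.to_numpy())[0]
        fit = bs.gibbs_fit(bundle, bs.SamplerConfig(6000, 2000, seed=8),
                           train_rows=train)
        contrib = bs.block_contribution(fit, "g", rows=np.where(unseen)[0])
        seen_scale = np.abs(bs.block_contribution(fit, "g")).max()
        assert np.abs(contrib).max() < 0.15 * max(seen_scale, 1.0)

    def test_wg_twin_borrowing(self, rng):
        """A masked line that is genomically identical to an observed twin
        inherits the twin's genetic prediction through the kernel."""
        n = 20
        lines = [f"L{i}" for i in range(n)]
        K = np.eye(n)
        K[0, 1] = K[1, 0] = 1.0  # lines 0 and 1 identical
        kin = km.ensure_pd(km.Kinship(K, lines, "genomic"), jitter=1e-6)
        g_eig = np.linalg.eigh(kin.values)
        g_true = (g_eig[1] * np.sqrt(np.clip(g_eig[0], 0, None))) @ rng.standard_normal(n)
        rows = []
        for e in ["E1", "E2"]:
            for i, l in enumerate(lines):
                rows.append(
                    {"environment": e, "genotype": l,
                     "yield": 5.0 + g_true[i] + 0.05 * rng.standard_normal()}
                )
        t = pd.DataFrame(rows)
        bundle = mc.compile(mc.ModelSpec("M1", "WG"), t, kinships={"G": kin})
        mask = (t.genotype == "L0").to_numpy()
        fit = bs.gibbs_fit(
            bundle, bs.SamplerConfig(6000, 2000, seed=9),
            train_rows=np.where(~mask)[0],
        )
        contrib = bs.block_contribution(fit, "g")
        twin_rows = (t.genotype == "L1").to_numpy()
        assert np.abs(contrib[mask].mean() - contrib[twin_rows].mean()) < 0.2 * max(
            1.0, np.abs(contrib[twin_rows].mean())
        )


class TestReconstructBeta:
    def test_rejects_conventional_fit(self, rng):
        t, lines = _make_table(rng)
        bundle = mc.compile(mc.ModelSpec("M3", "WO", L=7, S=7), t)
        fit = bs.gibbs_fit(bundle, bs.SamplerConfig(200, 100, seed=0))
        with pytest.raises(ValueError, match="functional"):
            bs.reconstruct_beta_function(fit)

    def test_whiten_expand_reproject_round_trip(self, rng):
        from bandreg import fda_basis as fb

        t, lines = _make_table(rng)
        bundle = mc.compile(mc.ModelSpec("M5", "WO", L=9, S=9), t)
        fit = bs.gibbs_fit(bundle, bs.SamplerConfig(500, 200, seed=1))
        rec = bs.reconstruct_beta_function(fit)
        psi = bundle.artifacts["basis_psi"]
        dense = np.linspace(*psi.domain, 600)
        curve = fb.evaluate_basis(psi, dense) @ rec["d1"]
        Psi = fb.evaluate_basis(psi, dense)
        d_back = np.linalg.lstsq(Psi, curve, rcond=None)[0]
        assert np.allclose(d_back, rec["d1"], atol=1e-8)

    def test_zero_band_signal_gives_flat_beta(self):
        from bandreg import synthetic_data as sd

        cfg = sd.default_config(
            n_lines=100, trials=4, blocks_per_rep=5, n_bands=30,
            sigma2_func=0.0, sigma2_func_env=0.0, n_markers=200, seed=17,
        )
        _, markers = sd.simulate_pedigree_markers(cfg)
        kin = km.genomic_relationship(km.qc_markers(markers))
        table, truth = sd.simulate_second_stage_table(cfg, kin)
        bundle = mc.compile(mc.ModelSpec("M5", "WG"), table, kinships={"G": kin})
        fit = bs.gibbs_fit(bundle, bs.SamplerConfig(4000, 2000, seed=2))
        rec = bs.reconstruct_beta_function(fit)
        # the functional contribution stays inside the noise band: its
        # variation across cells is small relative to the response sd
        scores = next(b for b in bundle.blocks if b.name == "func").X
        contrib = scores @ fit.block_coef("func")
        assert contrib.std() < 0.25 * table["yield"].std()
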