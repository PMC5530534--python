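"""Gibbs sampler for the compiled prediction models.

Every compiled design block enters the sampler as a dense column block
with a shared prior: fixed-effect columns get independent normal priors
with a large fixed variance; random blocks (kernel line effects in their
kernel eigenbasis, G×E copies, band coefficients, whitened functional
scores) get i.i.d. normal priors whose common variance is updated from
its scaled inverse chi-square full conditional.  The residual variance
uses the same conjugate update but under a prior so concentrated near 1
(scale = df = 2e10) that it is effectively pinned: the second-stage
response is assumed to be pre-scaled by the square roots of its
inverse-variance weights, which makes a unit residual variance the
correct calibration.

Scaled inverse chi-square convention: ``σ² ~ S·Inv-χ²(df)`` means
``σ² = S/χ²_df`` up to the prior draw, density ``∝ (σ²)^{-(df/2+1)}
exp(-S/(2σ²))``, with mode ``S/(df+2)``.  The full conditional for a
block of k coefficients with sum of squares SS is
``(S + SS)/χ²_{df+k}``.

Coefficient updates are single-site (ridge-type) Gibbs sweeps over all
columns, compiled with numba; a seeded run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numba

from . import fda_basis
from .model_catalog import DesignBundle

__all__ = [
    "PriorConfig",
    "SamplerConfig",
    "PosteriorFit",
    "gibbs_fit",
    "predict",
    "block_contribution",
    "reconstruct_beta_function",
    "sample_scaled_inv_chi2",
]


@dataclass
class PriorConfig:
    """Prior hyper-parameters.

    ``block_scale``/``block_df`` override the per-block scaled-inv-χ²
    hyperparameters; when a block has no entry, a weakly informative
    default is used: df = 5 and scale chosen so each random block's
    prior mode corresponds to an equal share of half the response
    variance that remains after the fixed effects, divided by the
    block's mean column sum of squares — the explained-variance
    partition rule of Bayesian whole-genome regression software.
    """

    fixed_var: float = 1.0e4
    residual_scale: float = 2.0e10
    residual_df: float = 2.0e10
    block_df: dict[str, float] = field(default_factory=dict)
    block_scale: dict[str, float] = field(default_factory=dict)
    default_df: float = 5.0
    default_mode_fraction: float = 0.5


@dataclass
class SamplerConfig:
    iterations: int = 30_000
    burn_in: int = 20_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must be in [0, iterations)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorFit:
    """Posterior summaries of a Gibbs run."""

    coef_mean: np.ndarray
    coef_sd: np.ndarray
    block_slices: dict[str, slice]
    variance_chains: dict[str, np.ndarray]  # per random block + "residual"
    fitted: np.ndarray  # all bundle rows at posterior means (unweighted scale)
    bundle: DesignBundle
    config: SamplerConfig

    def block_coef(self, name: str) -> np.ndarray:
        return self.coef_mean[self.block_slices[name]]


def sample_scaled_inv_chi2(
    rng: np.random.Generator, scale: float, df: float
) -> float:
    """One draw from S·Inv-χ²(df) (mode S/(df+2))."""
    return scale / rng.chisquare(df)


@numba.njit(cache=True)
def _gibbs_core(
    y, X, block_start, block_end, block_fixed, block_joint,
    prior_scale, prior_df, res_scale, res_df, fixed_var,
    n_iter, burn_in, thin, seed,
):  # pragma: no cover - exercised through gibbs_fit
    np.random.seed(seed)
    n, P = X.shape
    nb = block_start.shape[0]
    xtx = np.empty(P)
    for j in range(P):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s
    # Gram matrices for jointly updated blocks, packed side by side
    max_k = 0
    for b in range(nb):
        if block_joint[b]:
            k = block_end[b] - block_start[b]
            if k > max_k:
                max_k = k
    grams = np.zeros((max_k, max_k * nb))
    for b in range(nb):
        if block_joint[b]:
            s0, k = block_start[b], block_end[b] - block_start[b]
            for a in range(k):
                for c in range(a, k):
                    s = 0.0
                    for i in range(n):
                        s += X[i, s0 + a] * X[i, s0 + c]
                    grams[a, b * max_k + c] = s
                    grams[c, b * max_k + a] = s

    beta = np.zeros(P)
    sigma2 = np.empty(nb)
    for b in range(nb):
        sigma2[b] = prior_scale[b] / (prior_df[b] + 2.0)
    sigma2_e = res_scale / (res_df + 2.0)
    e = y.copy()
    n_kept = (n_iter - burn_in + thin - 1) // thin
    var_chain = np.zeros((n_kept, nb))
    res_chain = np.zeros(n_kept)
    beta_sum = np.zeros(P)
    beta_sumsq = np.zeros(P)
    kept = 0
    for it in range(n_iter):
        for b in range(nb):
            v = fixed_var if block_fixed[b] else sigma2[b]
            s0, s1 = block_start[b], block_end[b]
            k = s1 - s0
            if block_joint[b]:
                # joint multivariate-normal draw of the whole block
                rhs = np.zeros(k)
                for a in range(k):
                    s = 0.0
                    for i in range(n):
                        s += X[i, s0 + a] * e[i]
                    for c in range(k):
                        s += grams[a, b * max_k + c] * beta[s0 + c]
                    rhs[a] = s / sigma2_e
                A = np.empty((k, k))
                for a in range(k):
                    for c in range(k):
                        A[a, c] = grams[a, b * max_k + c] / sigma2_e
                    A[a, a] += 1.0 / v
                L = np.linalg.cholesky(A)
                mean = np.linalg.solve(A, rhs)
                z = np.empty(k)
                for a in range(k):
                    z[a] = np.random.normal(0.0, 1.0)
                # solve L' x = z by back substitution for a draw ~ N(0, A^-1)
                x = np.zeros(k)
                for a in range(k - 1, -1, -1):
                    s = z[a]
                    for c in range(a + 1, k):
                        s -= L[c, a] * x[c]
                    x[a] = s / L[a, a]
                for a in range(k):
                    bn = mean[a] + x[a]
                    d = bn - beta[s0 + a]
                    if d != 0.0:
                        for i in range(n):
                            e[i] -= X[i, s0 + a] * d
                    beta[s0 + a] = bn
            else:
                for j in range(s0, s1):
                    bj = beta[j]
                    if xtx[j] == 0.0:
                        # no support in the training rows: prior draw
                        beta[j] = np.random.normal(0.0, np.sqrt(v))
                        continue
                    rhs = 0.0
                    for i in range(n):
                        rhs += X[i, j] * e[i]
                    rhs += xtx[j] * bj
                    prec = xtx[j] / sigma2_e + 1.0 / v
                    mean = rhs / sigma2_e / prec
                    bn = mean + np.random.normal(0.0, 1.0) / np.sqrt(prec)
                    d = bn - bj
                    if d != 0.0:
                        for i in range(n):
                            e[i] -= X[i, j] * d
                    beta[j] = bn
        for b in range(nb):
            if block_fixed[b]:
                continue
            ss = 0.0
            for j in range(block_start[b], block_end[b]):
                ss += beta[j] * beta[j]
            k = block_end[b] - block_start[b]
            sigma2[b] = (prior_scale[b] + ss) / np.random.chisquare(prior_df[b] + k)
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma2_e = (res_scale + sse) / np.random.chisquare(res_df + n)
        if not np.isfinite(sigma2_e):
            raise ValueError("sampler state became non-finite")
        if it >= burn_in and (it - burn_in) % thin == 0:
            for b in range(nb):
                var_chain[kept, b] = sigma2[b]
            res_chain[kept] = sigma2_e
            for j in range(P):
                beta_sum[j] += beta[j]
                beta_sumsq[j] += beta[j] * beta[j]
            kept += 1
    return beta_sum / kept, beta_sumsq / kept, var_chain, res_chain


def gibbs_fit(
    bundle: DesignBundle,
    config: SamplerConfig,
    priors: PriorConfig | None = None,
    train_rows: np.ndarray | None = None,
    joint_block_max: int = 128,
) -> PosteriorFit:
    """Fit a compiled bundle by Gibbs sampling.

    ``train_rows`` restricts the likelihood to a subset of the bundle's
    rows (the cross-validation training set); predictions for all rows
    remain available from the posterior coefficient means.  When the
    bundle carries inverse-variance weights, training rows of both the
    response and the design are pre-scaled by ``sqrt(w)`` so the pinned
    unit residual variance realizes ``var(γ_ij) = 1/w_ij``.
    """
    priors = priors or PriorConfig()
    if not np.all(np.isfinite(bundle.y)):
        raise ValueError("response contains non-finite values")

    X_full = bundle.design_matrix()
    rows = np.arange(bundle.n) if train_rows is None else np.asarray(train_rows)
    Xw = X_full[rows].copy()
    yw = bundle.y[rows].copy()
    if bundle.weights is not None:
        sw = np.sqrt(bundle.weights[rows])
        Xw *= sw[:, None]
        yw = yw * sw

    block_fixed = np.array([b.prior == "fixed" for b in bundle.blocks])
    block_slices: dict[str, slice] = {}
    starts, ends = [], []
    off = 0
    for b in bundle.blocks:
        block_slices[b.name] = slice(off, off + b.X.shape[1])
        starts.append(off)
        ends.append(off + b.X.shape[1])
        off += b.X.shape[1]
    block_start = np.array(starts, dtype=np.int64)
    block_end = np.array(ends, dtype=np.int64)
    # small blocks are drawn jointly from their multivariate-normal full
    # conditional (fast mixing between overlapping blocks); large blocks
    # (kernel eigenbases, raw band blocks) use single-site sweeps
    sizes = block_end - block_start
    block_joint = sizes <= joint_block_max

    n_random = max(int((~block_fixed).sum()), 1)
    # response variance left after the fixed blocks, used to calibrate
    # the weakly informative variance priors
    Xfix = np.hstack(
        [Xw[:, block_slices[b.name]] for b in bundle.blocks if b.prior == "fixed"]
    ) if np.any(block_fixed) else None
    if Xfix is not None and Xfix.shape[1] > 0:
        coef, *_ = np.linalg.lstsq(Xfix, yw, rcond=None)
        vy = float(np.var(yw - Xfix @ coef))
    else:
        vy = float(np.var(yw))
    scale = np.empty(len(bundle.blocks))
    df = np.empty(len(bundle.blocks))
    for g, b in enumerate(bundle.blocks):
        df[g] = priors.block_df.get(b.name, priors.default_df)
        if b.name in priors.block_scale:
            scale[g] = priors.block_scale[b.name]
            continue
        sl = block_slices[b.name]
        msx = float(np.mean(np.sum(Xw[:, sl] ** 2, axis=0)))
        msx = max(msx, 1e-12)
        mode = (
            priors.default_mode_fraction * max(vy, 1e-12) * Xw.shape[0]
            / (n_random * msx)
        )
        scale[g] = mode * (df[g] + 2.0)

    beta_mean, beta_msq, var_chain, res_chain = _gibbs_core(
        np.ascontiguousarray(yw),
        np.asfortranarray(Xw),
        block_start,
        block_end,
        block_fixed,
        block_joint,
        scale,
        df,
        priors.residual_scale,
        priors.residual_df,
        priors.fixed_var,
        config.iterations,
        config.burn_in,
        config.thin,
        config.seed,
    )
    coef_sd = np.sqrt(np.maximum(beta_msq - beta_mean**2, 0.0))
    chains = {
        b.name: var_chain[:, g]
        for g, b in enumerate(bundle.blocks)
        if b.prior == "random"
    }
    chains["residual"] = res_chain
    fitted = X_full @ beta_mean
    return PosteriorFit(
        coef_mean=beta_mean,
        coef_sd=coef_sd,
        block_slices=block_slices,
        variance_chains=chains,
        fitted=fitted,
        bundle=bundle,
        config=config,
    )


def predict(fit: PosteriorFit, rows: np.ndarray | None = None) -> np.ndarray:
    """Predicted cell values at the posterior coefficient means.

    ``rows`` indexes the bundle's rows (default: all).  Unobserved lines
    borrow through the kernel eigenbasis columns; with the identity
    kernel there is no borrowing and their line contribution is zero in
    expectation.
    """
    if rows is None:
        return fit.fitted.copy()
    return fit.fitted[np.asarray(rows)]


def block_contribution(fit: PosteriorFit, name: str, rows=None) -> np.ndarray:
    """Contribution of one design block to the fitted values."""
    sl = fit.block_slices[name]
    X = fit.bundle.blocks[[b.name for b in fit.bundle.blocks].index(name)].X
    contrib = X @ fit.coef_mean[sl]
    return contrib if rows is None else contrib[np.asarray(rows)]


def reconstruct_beta_function(
    fit: PosteriorFit, grid: np.ndarray | None = None
) -> dict:
    """Evaluate the posterior-mean functional coefficient curves.

    Un-whitens the sampled basis coefficients (``d = P^{-1/2} d_w``) and
    expands them in the coefficient basis ψ on ``grid`` (default: the
    band wavelengths the model was compiled on).  Returns ``beta1`` and,
    for band×environment models, ``beta2`` per environment.

    The decomposition into a common coefficient and environment-specific
    deviations is only identified up to a shift between them; the
    returned curves use the sum-to-zero-over-environments convention
    (the environment mean of ``beta2`` is folded into ``beta1``).
    """
    art = fit.bundle.artifacts
    if "basis_psi" not in art:
        raise ValueError("fit does not come from a functional model")
    psi = art["basis_psi"]
    W = art["whitener"]
    if grid is None:
        grid = art["wavelengths"]
    Psi = fda_basis.evaluate_basis(psi, grid)
    d1 = W @ fit.block_coef("func")
    out = {"grid": np.asarray(grid), "beta1": Psi @ d1, "d1": d1}
    if "func_env" in fit.block_slices:
        d2w = fit.block_coef("func_env")
        S = psi.size
        out["beta2"] = {}
        out["d2"] = {}
        for i, env in enumerate(fit.bundle.envs):
            d2 = W @ d2w[i * S:(i + 1) * S]
            out["beta2"][env] = Psi @ d2
            out["d2"][env] = d2
        # identifiability convention: environment mean folded into beta1
        b2_mean = np.mean([out["beta2"][e] for e in fit.bundle.envs], axis=0)
        d2_mean = np.mean([out["d2"][e] for e in fit.bundle.envs], axis=0)
        out["beta1"] = out["beta1"] + b2_mean
        out["d1"] = out["d1"] + d2_mean
        for e in fit.bundle.envs:
            out["beta2"][e] = out["beta2"][e] - b2_mean
            out["d2"][e] = out["d2"][e] - d2_mean
    return out
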