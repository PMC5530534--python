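"""First-stage adjustment of alpha-lattice field trials.

Plot-level data from a resolvable incomplete-block (alpha-lattice) design
are adjusted per environment with the mixed model

    y = mu_(genotype) + trial + rep(trial) + block(trial, rep) + error,

where the genotype-in-environment means ``mu_ij`` are fixed and the
design terms are random with environment-specific variances.  Variance
components are estimated by EM-REML (with Aitken acceleration), the
genotype means by generalized least squares (BLUEs), and each mean
carries an inverse-variance weight ``w_ij = [Psi_i^{-1}]_jj`` with
``Psi_i = (X' Sigma^{-1} X)^{-1}``, for use in the second-stage genomic
prediction models.  The same adjustment is applied to the yield trait
and to every reflectance band at every time-point; the second-stage
table stacks one row per (environment, genotype) with the yield BLUE,
its weight, and all band BLUEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "VarComponents",
    "StageOneResult",
    "EnvDesign",
    "reml_varcomps",
    "blues",
    "adjust_environment",
    "assemble_second_stage",
    "band_columns",
]

PLOT_COLUMNS = ["environment", "trial", "rep", "block", "genotype"]

_RANDOM_TERMS = ("trial", "rep", "block")


@dataclass
class VarComponents:
    """Environment-specific variance components (trait units squared)."""

    sigma2_rep: float
    sigma2_trial: float
    sigma2_block: float
    sigma2_error: float
    loglik: float = np.nan
    n_iter: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "rep": self.sigma2_rep,
            "trial": self.sigma2_trial,
            "block": self.sigma2_block,
            "error": self.sigma2_error,
        }


@dataclass
class StageOneResult:
    """BLUEs and inverse-variance weights for one environment and trait."""

    environment: str
    trait: str
    blues: pd.Series  # indexed by genotype
    weights: pd.Series  # diagonal of Psi^{-1}
    varcomps: VarComponents


def band_columns(columns) -> list[str]:
    """Band covariate columns, named ``band_<wavelength>_t<timepoint>``."""
    return [c for c in columns if c.startswith("band_")]


class EnvDesign:
    """Precompiled design matrices for one environment's plot table.

    Fixed effects: one column per genotype (cell means).  Random terms:
    trial, rep-within-trial, block-within-trial-and-rep.  The cross
    products are cached so REML and GLS can be re-run cheaply for every
    trait measured on the same layout.
    """

    def __init__(self, env_table: pd.DataFrame):
        for c in PLOT_COLUMNS:
            if c not in env_table.columns:
                raise ValueError(f"plot table is missing column {c!r}")
        t = env_table.reset_index(drop=True)
        self.table = t
        self.n = len(t)
        self.genotypes = sorted(t["genotype"].unique())
        gidx = {g: i for i, g in enumerate(self.genotypes)}
        self._geno_codes = t["genotype"].map(gidx).to_numpy()
        self.X = np.zeros((self.n, len(self.genotypes)))
        self.X[np.arange(self.n), self._geno_codes] = 1.0

        def incidence(keys: list[str]) -> np.ndarray:
            labels = t[keys].astype(str).agg("/".join, axis=1)
            levels = sorted(labels.unique())
            li = {l: i for i, l in enumerate(levels)}
            Z = np.zeros((self.n, len(levels)))
            Z[np.arange(self.n), labels.map(li)] = 1.0
            return Z

        self.Z = {
            "trial": incidence(["trial"]),
            "rep": incidence(["trial", "rep"]),
            "block": incidence(["trial", "rep", "block"]),
        }
        self.q = {k: Z.shape[1] for k, Z in self.Z.items()}
        Zall = np.hstack([self.Z[k] for k in _RANDOM_TERMS])
        self.Zall = Zall
        self.XtX = self.X.T @ self.X
        self.XtZ = self.X.T @ Zall
        self.ZtZ = Zall.T @ Zall
        self.p = self.X.shape[1]
        if np.linalg.matrix_rank(self.XtX) < self.p:
            raise ValueError("genotype design is rank-deficient")
        # slices of the stacked random-effect vector per term
        self.slices = {}
        off = 0
        for k in _RANDOM_TERMS:
            self.slices[k] = slice(off, off + self.q[k])
            off += self.q[k]
        self.q_total = off
        # genotype equations are diagonal; absorb them once so each
        # likelihood evaluation factorizes only the random-effect block
        self.xtx_diag = np.diag(self.XtX).copy()
        self.A0 = self.XtZ.T @ (self.XtZ / self.xtx_diag[:, None])

    # -- REML ---------------------------------------------------------------

    def _mme(self, y, s2, s2e, need_inverse=True):
        """Solve Henderson's mixed-model equations; return solution pieces."""
        d = np.concatenate(
            [np.full(self.q[k], s2e / s2[k]) for k in _RANDOM_TERMS]
        )
        M = np.block([[self.XtX, self.XtZ], [self.XtZ.T, self.ZtZ + np.diag(d)]])
        rhs = np.concatenate([self.X.T @ y, self.Zall.T @ y])
        cf = cho_factor(M, lower=True)
        sol = cho_solve(cf, rhs)
        logdet_M = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Minv = cho_solve(cf, np.eye(M.shape[0])) if need_inverse else None
        return sol, Minv, logdet_M, rhs

    def _profile_loglik(self, Xty, Zty, yty, s2, s2e):
        """REML log-likelihood via absorption of the genotype equations."""
        d = np.concatenate(
            [np.full(self.q[k], s2e / s2[k]) for k in _RANDOM_TERMS]
        )
        S = self.ZtZ - self.A0 + np.diag(d)
        cf = cho_factor(S, lower=True)
        rhs_u = Zty - self.XtZ.T @ (Xty / self.xtx_diag)
        u = cho_solve(cf, rhs_u)
        b = (Xty - self.XtZ @ u) / self.xtx_diag
        logdet_M = float(
            np.sum(np.log(self.xtx_diag)) + 2.0 * np.sum(np.log(np.diag(cf[0])))
        )
        ypy = (yty - b @ Xty - u @ Zty) / s2e
        logdet = (
            (self.n - self.p - self.q_total) * np.log(s2e)
            + sum(self.q[k] * np.log(s2[k]) for k in _RANDOM_TERMS)
            + logdet_M
        )
        return -0.5 * (logdet + ypy)

    def _reml_loglik(self, y, sol, logdet_M, rhs, s2, s2e):
        n, p, q = self.n, self.p, self.q_total
        ypy = (y @ y - sol @ rhs) / s2e
        logdet = (
            (n - p - q) * np.log(s2e)
            + sum(self.q[k] * np.log(s2[k]) for k in _RANDOM_TERMS)
            + logdet_M
        )
        return -0.5 * (logdet + ypy)

    def reml(
        self,
        y: np.ndarray,
        start: dict[str, float] | None = None,
        tol: float = 1e-8,
        max_iter: int = 200,
    ) -> VarComponents:
        """REML by quasi-Newton optimization on log variances.

        The profile REML log-likelihood is evaluated through the
        mixed-model-equation factorization (one Cholesky per evaluation)
        and maximized over ``log σ²`` with L-BFGS-B; a floor on each
        variance acts as the boundary, and components that finish on the
        floor are reported as exactly 0.  Convergence is declared when
        the log-likelihood change falls below ``tol``.
        """
        from scipy.optimize import minimize

        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError("trait vector length does not match the design")
        vy = float(np.var(y))
        if vy == 0.0:
            vy = 1.0
        floor = 1e-8 * vy
        if start is None:
            x0 = np.log([0.1 * vy] * 3 + [0.5 * vy])
        else:
            x0 = np.log(
                [max(float(start[k]), floor) for k in _RANDOM_TERMS]
                + [max(float(start["error"]), floor)]
            )

        Xty = self.X.T @ y
        Zty = self.Zall.T @ y
        yty = float(y @ y)

        def negll_grad(x):
            """-loglik and its exact gradient on the log-variance scale.

            Uses the standard REML derivative identities
            ``dl/dσ_c² = -½[tr(P Z_c Z_c') - ||Z_c' P y||²]`` with the
            traces read off the absorbed mixed-model equations.
            """
            s2 = dict(zip(_RANDOM_TERMS, np.exp(x[:3])))
            s2e = float(np.exp(x[3]))
            d_vec = np.concatenate(
                [np.full(self.q[k], s2e / s2[k]) for k in _RANDOM_TERMS]
            )
            try:
                S = self.ZtZ - self.A0 + np.diag(d_vec)
                cf = cho_factor(S, lower=True)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros(4)
            rhs_u = Zty - self.XtZ.T @ (Xty / self.xtx_diag)
            u = cho_solve(cf, rhs_u)
            b = (Xty - self.XtZ @ u) / self.xtx_diag
            logdet_M = float(
                np.sum(np.log(self.xtx_diag))
                + 2.0 * np.sum(np.log(np.diag(cf[0])))
            )
            ypy = (yty - b @ Xty - u @ Zty) / s2e
            ll = -0.5 * (
                (self.n - self.p - self.q_total) * np.log(s2e)
                + sum(self.q[k] * np.log(s2[k]) for k in _RANDOM_TERMS)
                + logdet_M
                + ypy
            )
            if not np.isfinite(ll):
                return 1e12, np.zeros(4)
            Sinv_diag = np.diag(cho_solve(cf, np.eye(S.shape[0])))
            e = y - b[self._geno_codes] - self.Zall @ u
            ete = float(e @ e)
            grad = np.empty(4)
            tr_ratio_sum = 0.0
            for i, k in enumerate(_RANDOM_TERMS):
                sl = self.slices[k]
                tr_cond = s2e * float(Sinv_diag[sl].sum())  # tr Var(u_c|y)
                tr_ratio_sum += tr_cond / s2[k]
                uk = u[sl]
                trP = (self.q[k] - tr_cond / s2[k]) / s2[k]
                grad[i] = -0.5 * (trP - (uk @ uk) / s2[k] ** 2)
            trP_e = (self.n - self.p - self.q_total + tr_ratio_sum) / s2e
            grad[3] = -0.5 * (trP_e - ete / s2e**2)
            # chain rule to the log scale
            scale = np.array([s2[k] for k in _RANDOM_TERMS] + [s2e])
            return -ll, -grad * scale

        bounds = [(np.log(floor), np.log(1e4 * vy))] * 4
        opts = {"maxiter": max_iter, "ftol": 1e-12, "gtol": tol}
        res = minimize(
            negll_grad, x0, method="L-BFGS-B", jac=True, bounds=bounds,
            options=opts,
        )
        def projected_grad(r):
            # at an active bound, a gradient pointing out of the feasible
            # region is not an optimality violation
            lo = np.array([b[0] for b in bounds])
            hi = np.array([b[1] for b in bounds])
            g = np.asarray(r.jac, dtype=float).copy()
            g[(r.x <= lo + 1e-9) & (g > 0)] = 0.0
            g[(r.x >= hi - 1e-9) & (g < 0)] = 0.0
            return np.abs(g).max()

        if not res.success:
            # a stalled line search at round-off level is acceptable if the
            # projected gradient is already tiny; otherwise restart once
            if projected_grad(res) > 1e-4:
                res = minimize(
                    negll_grad, res.x, method="L-BFGS-B", jac=True,
                    bounds=bounds, options=opts,
                )
            if res.status == 1:
                raise RuntimeError(
                    f"REML did not converge in {max_iter} iterations"
                )
            if not res.success and projected_grad(res) > 1e-4:
                raise RuntimeError(f"REML optimization failed: {res.message}")
        s2 = dict(zip(_RANDOM_TERMS, np.exp(res.x[:3])))
        s2e = float(np.exp(res.x[3]))
        # boundary truncation: report near-floor components as exactly 0
        out = {k: (0.0 if v <= 2 * floor else v) for k, v in s2.items()}
        return VarComponents(
            sigma2_rep=out["rep"],
            sigma2_trial=out["trial"],
            sigma2_block=out["block"],
            sigma2_error=s2e,
            loglik=-res.fun,
            n_iter=int(res.nfev),
        )

    def reml_loglik_dense(self, y: np.ndarray, vc: VarComponents) -> float:
        """Dense-matrix REML log-likelihood (independent of the MME path)."""
        Sigma = self.sigma(vc)
        cf = cho_factor(Sigma, lower=True)
        Si_y = cho_solve(cf, y)
        Si_X = cho_solve(cf, self.X)
        XtSiX = self.X.T @ Si_X
        beta = np.linalg.solve(XtSiX, self.X.T @ Si_y)
        resid = y - self.X @ beta
        ypy = resid @ cho_solve(cf, resid)
        logdet_V = 2.0 * np.sum(np.log(np.diag(cf[0])))
        logdet_XVX = np.linalg.slogdet(XtSiX)[1]
        return -0.5 * (logdet_V + logdet_XVX + ypy)

    def sigma(self, vc: VarComponents) -> np.ndarray:
        """Plot covariance ``Sigma = sigma_e^2 I + sum_c sigma_c^2 Z_c Z_c'``."""
        S = vc.sigma2_error * np.eye(self.n)
        S += vc.sigma2_trial * (self.Z["trial"] @ self.Z["trial"].T)
        S += vc.sigma2_rep * (self.Z["rep"] @ self.Z["rep"].T)
        S += vc.sigma2_block * (self.Z["block"] @ self.Z["block"].T)
        return S

    # -- GLS BLUEs ----------------------------------------------------------

    def gls_blues(self, y: np.ndarray, vc: VarComponents):
        """Generalized least-squares genotype means and their weights.

        Uses the Woodbury identity on the random-effect block, so no
        plot-by-plot covariance matrix is formed; boundary (zero)
        variance components simply drop their columns.
        """
        if vc.sigma2_error <= 0:
            raise ValueError("error variance must be positive for GLS")
        s2e = vc.sigma2_error
        comp = {"trial": vc.sigma2_trial, "rep": vc.sigma2_rep,
                "block": vc.sigma2_block}
        keep = np.concatenate(
            [
                np.full(self.q[k], comp[k] > 0)
                for k in _RANDOM_TERMS
            ]
        )
        if keep.any():
            d = np.concatenate(
                [
                    np.full(self.q[k], s2e / comp[k] if comp[k] > 0 else np.inf)
                    for k in _RANDOM_TERMS
                ]
            )[keep]
            ZtZk = self.ZtZ[np.ix_(keep, keep)]
            cf = cho_factor(ZtZk + np.diag(d), lower=True)
            XtZk = self.XtZ[:, keep]
            Ztyk = (self.Zall[:, keep]).T @ y
            XtSiX = (self.XtX - XtZk @ cho_solve(cf, XtZk.T)) / s2e
            XtSiy = (self.X.T @ y - XtZk @ cho_solve(cf, Ztyk)) / s2e
        else:
            XtSiX = self.XtX / s2e
            XtSiy = self.X.T @ y / s2e
        mu = np.linalg.solve(XtSiX, XtSiy)
        weights = np.diag(XtSiX).copy()
        return mu, weights


# ---------------------------------------------------------------------------
# module-level operations


def reml_varcomps(env_table: pd.DataFrame, trait: str, **kw) -> VarComponents:
    """REML variance components for one environment and trait."""
    design = EnvDesign(env_table)
    return design.reml(env_table[trait].to_numpy(dtype=float), **kw)


def blues(
    env_table: pd.DataFrame, trait: str, varcomps: VarComponents
) -> StageOneResult:
    """GLS BLUEs of genotype means with inverse-variance weights."""
    design = EnvDesign(env_table)
    mu, w = design.gls_blues(env_table[trait].to_numpy(dtype=float), varcomps)
    env = str(env_table["environment"].iloc[0])
    return StageOneResult(
        environment=env,
        trait=trait,
        blues=pd.Series(mu, index=design.genotypes),
        weights=pd.Series(w, index=design.genotypes),
        varcomps=varcomps,
    )


def adjust_environment(
    env_table: pd.DataFrame,
    traits: list[str],
    band_tol: float = 1e-6,
    band_max_iter: int = 300,
) -> dict[str, StageOneResult]:
    """Run REML + BLUEs for every trait of one environment.

    The first trait (yield) is fitted at full tolerance; band traits use
    a slightly looser tolerance.  The design matrices and their cross
    products are compiled once and shared across all traits.
    """
    design = EnvDesign(env_table)
    env = str(env_table["environment"].iloc[0])
    out: dict[str, StageOneResult] = {}
    for i, trait in enumerate(traits):
        y = env_table[trait].to_numpy(dtype=float)
        if i == 0:
            vc = design.reml(y)
        else:
            vc = design.reml(y, tol=band_tol, max_iter=band_max_iter)
        mu, w = design.gls_blues(y, vc)
        out[trait] = StageOneResult(
            environment=env,
            trait=trait,
            blues=pd.Series(mu, index=design.genotypes),
            weights=pd.Series(w, index=design.genotypes),
            varcomps=vc,
        )
    return out


def assemble_second_stage(
    results_by_env: dict[str, dict[str, StageOneResult]],
    yield_trait: str = "yield",
    drop_genotypes: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Stack per-environment BLUEs into the second-stage table.

    One row per (environment, genotype); columns: ``environment``,
    ``genotype``, the yield BLUE, every band BLUE (wavelength-major
    within time-point), and the yield weight as a trailing companion
    column.  Check genotypes participate in the first stage but are
    dropped here.
    """
    frames = []
    for env in sorted(results_by_env):
        res = results_by_env[env]
        if yield_trait not in res:
            raise ValueError(f"environment {env!r} has no {yield_trait!r} result")
        bands = [t for t in res if t != yield_trait]
        genos = [g for g in res[yield_trait].blues.index if g not in drop_genotypes]
        cols = {yield_trait: res[yield_trait].blues.reindex(genos)}
        for b in bands:
            vals = res[b].blues.reindex(genos)
            if vals.isna().any():
                g = vals.index[vals.isna().argmax()]
                raise ValueError(f"genotype {g!r} has no BLUE for {b!r} in {env!r}")
            cols[b] = vals
        cols["weight_yield"] = res[yield_trait].weights.reindex(genos)
        frame = pd.DataFrame(cols)
        frame.insert(0, "genotype", frame.index)
        frame.insert(0, "environment", env)
        frames.append(frame.reset_index(drop=True))
    table = pd.concat(frames, ignore_index=True)
    bands = band_columns(table.columns)
    ordered = ["environment", "genotype", yield_trait] + bands + ["weight_yield"]
    return table[ordered]
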