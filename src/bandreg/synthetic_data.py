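"""Synthetic multi-environment hyperspectral trials with known truth.

Generates complete experiments that mimic the structure of a wheat
phenomics trial: a pedigree and gene-dropped marker matrix, per-line
heritable reflectance curves on a wavelength grid, and an alpha-lattice
plot layout (trials × replicates × incomplete blocks) whose plot yields
are built from environment means, kernel-correlated line effects, G×E
effects, functional band effects ``∫ x_ij(k) β₁(k) dk + ∫ x_ij(k)
β₂i(k) dk``, design effects and plot error.  Every simulated effect is
returned as ground truth so recovery can be tested end to end.

Three independent random streams (genetics, curves, design) are spawned
from the seed so one component can be varied with the others fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import simpson

from .fda_basis import CurveSet
from .kinship import Kinship, MarkerMatrix, Pedigree

__all__ = [
    "SimConfig",
    "GroundTruth",
    "default_config",
    "paper_scale_config",
    "simulate_pedigree_markers",
    "simulate_curves",
    "simulate_trial",
    "simulate_second_stage_table",
    "simulate_experiment",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one synthetic experiment.

    The desk-scale defaults (300 lines, 3 environments, 10 trials of
    3 replicates × 6 blocks of 5, 100 bands on [392, 851] nm, one
    time-point) preserve the full structure of the emulated field design
    at a size where complete analyses run in minutes.
    """

    n_lines: int = 300
    n_envs: int = 3
    trials: int = 10
    reps: int = 3
    blocks_per_rep: int = 6
    block_size: int = 5
    n_checks: int = 2
    n_bands: int = 100
    band_domain: tuple[float, float] = (392.0, 851.0)
    n_timepoints: int = 1
    # genetic and design variances (trait units squared, yield in t/ha)
    env_means: tuple[float, ...] = (6.0, 5.0, 4.0)
    sigma2_line: float = 0.30
    sigma2_gE: float = 0.10
    sigma2_trial: float = 0.05
    sigma2_rep: float = 0.03
    sigma2_block: float = 0.02
    sigma2_error: float = 0.10
    # functional band signal, parameterized by the variance its
    # contribution adds to cell yields (like the other components);
    # reflectance integrates realized canopy status, so in the emulated
    # studies it carries more yield information than the genome alone
    sigma2_func: float = 1.0
    sigma2_func_env: float = 0.5
    # reflectance curve generation
    curve_basis_size: int = 15
    curve_herit_sd: float = 0.05
    curve_nonherit_sd: float = 0.03
    curve_env_sd: float = 0.05
    curve_env_shift_sd: float = 0.02
    band_noise_sd: float = 0.005
    band_design_sd: float = 0.005
    # pedigree / markers
    n_founders: int = 40
    n_generations: int = 2
    n_markers: int = 1000
    missing_rate: float = 0.02
    seed: int = 0

    def lines_per_trial(self) -> int:
        return self.blocks_per_rep * self.block_size

    def layout_lines(self) -> int:
        return self.trials * self.lines_per_trial()

    def validate(self) -> None:
        if self.n_lines > self.layout_lines():
            raise ValueError(
                f"{self.n_lines} lines do not fit a layout of "
                f"{self.trials} trials x {self.lines_per_trial()} lines"
            )
        if len(self.env_means) < self.n_envs:
            raise ValueError("need one environment mean per environment")


@dataclass
class GroundTruth:
    """All simulated effects, on their natural scales."""

    env_means: np.ndarray
    line_effects: pd.Series  # g_j
    gxe_effects: pd.DataFrame  # lines x envs
    beta1_grid: np.ndarray  # beta_1(k) on the band grid
    beta2_grid: pd.DataFrame  # bands x envs
    functional_part: pd.DataFrame  # lines x envs, the integral contribution
    wavelengths: np.ndarray
    design_effects: dict = field(default_factory=dict)


def default_config(**overrides) -> SimConfig:
    return replace(SimConfig(), **overrides)


def paper_scale_config(**overrides) -> SimConfig:
    """The emulated trial at full published scale.

    976 genotyped lines inside a 39-trial layout (39 × 30 = 1170 layout
    entries; the genotyped subset is carried to the second stage), three
    environments, 250 bands on [392, 851] nm, nine time-points.
    """
    base = SimConfig(
        n_lines=976,
        trials=39,
        n_bands=250,
        n_timepoints=9,
    )
    return replace(base, **overrides)


def _streams(seed: int):
    gen, curves, design = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(gen),
        np.random.default_rng(curves),
        np.random.default_rng(design),
    )


def _line_ids(n: int) -> list[str]:
    return [f"L{i + 1:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# pedigree and markers


def simulate_pedigree_markers(config: SimConfig) -> tuple[Pedigree, MarkerMatrix]:
    """Gene-drop a marker matrix through a random-mating pedigree.

    Founders carry allele frequencies ~ Uniform(0.05, 0.5); each of
    ``n_generations`` draws every individual from two random parents of
    the previous generation, transmitting one random allele per parent.
    The final generation are the study lines.  Missing dosages and a few
    deliberately high-missing and rare markers are injected so the QC
    filters have something to remove.
    """
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng, _, _ = _streams(config.seed)
    m = config.n_markers
    p = rng.uniform(0.05, 0.5, size=m)
    founders = [f"F{i + 1:03d}" for i in range(config.n_founders)]
    records: list[tuple[str, str | None, str | None]] = [
        (f, None, None) for f in founders
    ]
    alleles = {f: rng.binomial(1, p, size=(2, m)).astype(np.int8) for f in founders}
    prev = founders
    if config.n_generations == 0:
        lines = founders[: config.n_lines]
        if len(lines) < config.n_lines:
            raise ValueError("not enough founders for a 0-generation pedigree")
    else:
        lines = []
        for gen in range(1, config.n_generations + 1):
            size = config.n_lines
            ids = (
                _line_ids(size)
                if gen == config.n_generations
                else [f"X{gen}_{i + 1:04d}" for i in range(size)]
            )
            for ind in ids:
                sire, dam = rng.choice(prev, size=2, replace=True)
                records.append((ind, sire, dam))
                gam_s = alleles[sire][rng.integers(2, size=m), np.arange(m)]
                gam_d = alleles[dam][rng.integers(2, size=m), np.arange(m)]
                alleles[ind] = np.stack([gam_s, gam_d]).astype(np.int8)
            prev = ids
        lines = prev

    dosages = np.array([alleles[l].sum(axis=0) for l in lines], dtype=float)
    # injected QC fodder: 1% of markers mostly missing, 1% forced rare
    n_bad = max(1, m // 100)
    bad_missing = rng.choice(m, size=n_bad, replace=False)
    for j in bad_missing:
        rows = rng.choice(len(lines), size=int(0.4 * len(lines)), replace=False)
        dosages[rows, j] = np.nan
    rare = rng.choice(
        np.setdiff1d(np.arange(m), bad_missing), size=n_bad, replace=False
    )
    dosages[:, rare] = 0.0
    dosages[rng.integers(len(lines), size=n_bad), rare] = 1.0
    sprinkle = rng.random(dosages.shape) < config.missing_rate
    dosages[sprinkle] = np.nan
    markers = MarkerMatrix(
        dosages=dosages,
        line_ids=list(lines),
        marker_ids=[f"M{j + 1:05d}" for j in range(m)],
    )
    return Pedigree(records=records), markers


# ---------------------------------------------------------------------------
# reflectance curves


def _curve_basis_matrix(config: SimConfig, wavelengths: np.ndarray) -> np.ndarray:
    from .fda_basis import build_basis, evaluate_basis

    basis = build_basis("bspline", config.band_domain, config.curve_basis_size)
    return evaluate_basis(basis, wavelengths)


def _mean_curve(wavelengths: np.ndarray) -> np.ndarray:
    # a vegetation-like reflectance profile: low in the visible with a
    # green bump, red-edge rise toward the near infrared
    k = (wavelengths - wavelengths[0]) / (wavelengths[-1] - wavelengths[0])
    green = 0.08 * np.exp(-0.5 * ((k - 0.3) / 0.08) ** 2)
    red_edge = 0.35 / (1.0 + np.exp(-18.0 * (k - 0.7)))
    return 0.08 + green + red_edge


def simulate_curves(config: SimConfig, kinship: Kinship) -> CurveSet:
    """Smooth reflectance curves for every (env, line) cell.

    Each curve is the shared vegetation-like mean profile plus smooth
    basis-coefficient deviations from three sources: a heritable
    line-level component correlated across lines through the kinship
    (``curve_herit_sd``), an independent non-genetic line component
    (``curve_nonherit_sd``), and a line-by-environment component
    (``curve_env_sd``) — canopies of the same line look different under
    different water regimes, which is what makes bands measured in an
    environment informative about yield there.  A common environment
    shift moves all lines of an environment together; values are clipped
    to [0, 1] reflectance.
    """
    config.validate()
    _, rng, _ = _streams(config.seed)
    wl = np.linspace(*config.band_domain, config.n_bands)
    Phi = _curve_basis_matrix(config, wl)  # m x B
    mean = _mean_curve(wl)
    lines = kinship.line_ids
    n, B = len(lines), Phi.shape[1]
    w, V = np.linalg.eigh(kinship.values)
    Lk = V * np.sqrt(np.clip(w, 0, None))
    coefs = config.curve_herit_sd * (Lk @ rng.standard_normal((n, B)))
    coefs = coefs + config.curve_nonherit_sd * rng.standard_normal((n, B))
    env_shift = config.curve_env_shift_sd * rng.standard_normal((config.n_envs, B))
    values = []
    ids = []
    for e in range(config.n_envs):
        dev_env = config.curve_env_sd * rng.standard_normal((n, B))
        dev = (coefs + dev_env + env_shift[e]) @ Phi.T
        values.append(np.clip(mean + dev, 0.0, 1.0))
        ids.extend((f"E{e + 1}", l) for l in lines)
    return CurveSet(wavelengths=wl, values=np.vstack(values), curve_ids=ids)


# ---------------------------------------------------------------------------
# beta functions and the trial itself


def _beta_functions(config: SimConfig, curves: CurveSet):
    """Smooth true coefficient functions, calibrated against the curves.

    β₁ is a broad bump in the red-edge region minus an offset; each β₂i
    is a bump at an environment-specific wavelength with alternating
    sign, so the band effect genuinely differs across environments.  The
    fixed shapes are rescaled so that the variance their contribution
    ``∫ x_ij(k) β(k) dk`` adds across lines (averaged over environments)
    equals the configured ``sigma2_func`` / ``sigma2_func_env``: the
    generator is parameterized by contributed variance, not by raw
    coefficient amplitude.
    """
    wavelengths = curves.wavelengths
    a, b = wavelengths[0], wavelengths[-1]
    k = (wavelengths - a) / (b - a)
    shape1 = 2.0 * np.exp(-0.5 * ((k - 0.65) / 0.15) ** 2) - 0.5
    centers = np.linspace(0.25, 0.8, config.n_envs)
    shape2 = np.empty((len(wavelengths), config.n_envs))
    for i, c in enumerate(centers):
        sign = 1.0 if i % 2 == 0 else -1.0
        shape2[:, i] = sign * 2.5 * np.exp(-0.5 * ((k - c) / 0.10) ** 2)
    # the split between the common and the environment-specific
    # coefficient is only identified under a sum-to-zero-over-
    # environments convention; generate the truth in that convention
    shape2 -= shape2.mean(axis=1, keepdims=True)

    env_of = np.array([e for e, _ in curves.curve_ids])
    envs = sorted(set(env_of))

    def _within_env_var(shape_per_env) -> float:
        v = []
        for i, env in enumerate(envs):
            X = curves.values[env_of == env]
            contrib = simpson(X * shape_per_env[:, i], x=wavelengths, axis=1)
            v.append(np.var(contrib))
        return float(np.mean(v))

    v1 = _within_env_var(np.repeat(shape1[:, None], len(envs), axis=1))
    s1 = np.sqrt(config.sigma2_func / v1) if v1 > 0 and config.sigma2_func > 0 else 0.0
    v2 = _within_env_var(shape2)
    s2 = (
        np.sqrt(config.sigma2_func_env / v2)
        if v2 > 0 and config.sigma2_func_env > 0
        else 0.0
    )
    return s1 * shape1, s2 * shape2


def _alpha_lattice_layout(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Plot rows (trial, rep, block, genotype) for one environment.

    Lines are partitioned into trials; within each replicate the trial's
    lines are re-randomized into incomplete blocks (a fresh blocking per
    replicate, as in a resolvable alpha design).  Check genotypes are
    added once per replicate into a random block.
    """
    per_trial = config.lines_per_trial()
    layout_ids = _line_ids(config.layout_lines())
    checks = [f"CHK{c + 1}" for c in range(config.n_checks)]
    rows = []
    for t in range(config.trials):
        trial_lines = layout_ids[t * per_trial:(t + 1) * per_trial]
        for r in range(config.reps):
            perm = rng.permutation(trial_lines)
            for b in range(config.blocks_per_rep):
                for g in perm[b * config.block_size:(b + 1) * config.block_size]:
                    rows.append((f"T{t + 1:02d}", f"R{r + 1}", f"B{b + 1}", g))
            for c in checks:
                b = rng.integers(config.blocks_per_rep)
                rows.append((f"T{t + 1:02d}", f"R{r + 1}", f"B{b + 1}", c))
    return pd.DataFrame(rows, columns=["trial", "rep", "block", "genotype"])


def _functional_part(
    curves: CurveSet, beta1: np.ndarray, beta2: np.ndarray, envs: list[str]
) -> pd.DataFrame:
    wl = curves.wavelengths
    env_of = np.array([e for e, _ in curves.curve_ids])
    lines = [l for e, l in curves.curve_ids if e == envs[0]]
    out = pd.DataFrame(index=lines, columns=envs, dtype=float)
    for i, env in enumerate(envs):
        mask = env_of == env
        X = curves.values[mask]
        contrib = simpson(X * (beta1 + beta2[:, i]), x=wl, axis=1)
        out[env] = contrib
    return out


def simulate_trial(
    config: SimConfig, kinship: Kinship, curves: CurveSet
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate plot-level yields and band observations for all environments.

    Yield per plot: environment mean + kernel-correlated line effect +
    G×E + the functional band contribution of the cell + trial, replicate
    and block effects + plot error.  Band observations are the cell's
    true curve plus a plot-level scalar design offset and band noise.
    Checks get independent line effects and no genomic borrowing.
    """
    config.validate()
    rng_gen, _, rng_design = _streams(config.seed)
    envs = [f"E{e + 1}" for e in range(config.n_envs)]
    lines = kinship.line_ids
    checks = [f"CHK{c + 1}" for c in range(config.n_checks)]

    w, V = np.linalg.eigh(kinship.values)
    Lk = V * np.sqrt(np.clip(w, 0, None))
    g = pd.Series(
        np.sqrt(config.sigma2_line) * (Lk @ rng_gen.standard_normal(len(lines))),
        index=lines,
    )
    gxe = pd.DataFrame(
        np.sqrt(config.sigma2_gE)
        * (Lk @ rng_gen.standard_normal((len(lines), config.n_envs))),
        index=lines,
        columns=envs,
    )
    for c in checks:
        g[c] = np.sqrt(config.sigma2_line) * rng_gen.standard_normal()
    chk_gxe = pd.DataFrame(
        np.sqrt(config.sigma2_gE)
        * rng_gen.standard_normal((len(checks), config.n_envs)),
        index=checks,
        columns=envs,
    )
    gxe = pd.concat([gxe, chk_gxe])

    beta1, beta2 = _beta_functions(config, curves)
    func = _functional_part(curves, beta1, beta2, envs)
    # checks have no simulated curves; give them the functional value of
    # the mean curve so their plots stay on scale
    mean_curve = _mean_curve(curves.wavelengths)
    func = func.reindex(list(func.index) + checks)
    for i, env in enumerate(envs):
        func.loc[checks, env] = simpson(
            mean_curve * (beta1 + beta2[:, i]), x=curves.wavelengths
        )

    curve_lookup = {
        (e, l): curves.values[i] for i, (e, l) in enumerate(curves.curve_ids)
    }

    genotyped = set(lines[: config.n_lines])
    frames = []
    design_truth = {}
    for ei, env in enumerate(envs):
        layout = _alpha_lattice_layout(config, rng_design)
        layout = layout[
            layout["genotype"].isin(genotyped | set(checks))
        ].reset_index(drop=True)
        n = len(layout)
        tr_levels = layout["trial"].unique()
        rep_levels = (layout["trial"] + "/" + layout["rep"]).unique()
        blk_levels = (
            layout["trial"] + "/" + layout["rep"] + "/" + layout["block"]
        ).unique()
        t_eff = dict(zip(tr_levels, np.sqrt(config.sigma2_trial)
                         * rng_design.standard_normal(len(tr_levels))))
        r_eff = dict(zip(rep_levels, np.sqrt(config.sigma2_rep)
                         * rng_design.standard_normal(len(rep_levels))))
        b_eff = dict(zip(blk_levels, np.sqrt(config.sigma2_block)
                         * rng_design.standard_normal(len(blk_levels))))
        design_truth[env] = {"trial": t_eff, "rep": r_eff, "block": b_eff}
        eps = np.sqrt(config.sigma2_error) * rng_design.standard_normal(n)
        gvals = layout["genotype"].map(g).to_numpy()
        gevals = np.array([gxe.loc[gt, env] for gt in layout["genotype"]])
        fvals = np.array([func.loc[gt, env] for gt in layout["genotype"]])
        yvals = (
            config.env_means[ei]
            + gvals
            + gevals
            + fvals
            + layout["trial"].map(t_eff).to_numpy()
            + (layout["trial"] + "/" + layout["rep"]).map(r_eff).to_numpy()
            + (layout["trial"] + "/" + layout["rep"] + "/" + layout["block"])
            .map(b_eff).to_numpy()
            + eps
        )
        tbl = layout.copy()
        tbl.insert(0, "environment", env)
        tbl["yield"] = yvals
        # plot-level band observations for every time-point
        wl = curves.wavelengths
        base = np.array(
            [
                curve_lookup.get((env, gt), mean_curve)
                for gt in layout["genotype"]
            ]
        )
        for tp in range(1, config.n_timepoints + 1):
            offset = config.band_design_sd * rng_design.standard_normal((n, 1))
            noise = config.band_noise_sd * rng_design.standard_normal(base.shape)
            obs = np.clip(base + offset + noise, 0.0, 1.0)
            cols = [f"band_{wl[j]:.0f}_t{tp}" for j in range(len(wl))]
            tbl = pd.concat(
                [tbl, pd.DataFrame(obs, columns=cols, index=tbl.index)], axis=1
            )
        frames.append(tbl)

    table = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        env_means=np.asarray(config.env_means[: config.n_envs]),
        line_effects=g,
        gxe_effects=gxe,
        beta1_grid=beta1,
        beta2_grid=pd.DataFrame(beta2, index=curves.wavelengths, columns=envs),
        functional_part=func,
        wavelengths=curves.wavelengths,
        design_effects=design_truth,
    )
    return table, truth


def simulate_second_stage_table(
    config: SimConfig, kinship: Kinship, curves: CurveSet | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate directly at the (environment, genotype) cell level.

    Produces the second-stage layout — one row per cell with yield,
    unit weights and band columns — without the plot stage: cell yield =
    env mean + g + gE + functional part + cell residual with variance
    ``sigma2_error / reps`` (the precision a balanced first stage would
    deliver).  Used for structural checks and fast model-comparison
    experiments where the first-stage machinery is not under study.
    """
    config.validate()
    rng_gen, _, rng_design = _streams(config.seed)
    if curves is None:
        curves = simulate_curves(config, kinship)
    envs = [f"E{e + 1}" for e in range(config.n_envs)]
    lines = kinship.line_ids[: config.n_lines]

    w, V = np.linalg.eigh(kinship.values)
    Lk = V * np.sqrt(np.clip(w, 0, None))
    g = pd.Series(
        np.sqrt(config.sigma2_line) * (Lk @ rng_gen.standard_normal(len(kinship.line_ids))),
        index=kinship.line_ids,
    )
    gxe = pd.DataFrame(
        np.sqrt(config.sigma2_gE)
        * (Lk @ rng_gen.standard_normal((len(kinship.line_ids), config.n_envs))),
        index=kinship.line_ids,
        columns=envs,
    )
    beta1, beta2 = _beta_functions(config, curves)
    func = _functional_part(curves, beta1, beta2, envs)

    resid_sd = np.sqrt(config.sigma2_error / config.reps)
    curve_lookup = {
        (e, l): curves.values[i] for i, (e, l) in enumerate(curves.curve_ids)
    }
    wl = curves.wavelengths
    rows = []
    band_rows = []
    for ei, env in enumerate(envs):
        for l in lines:
            yv = (
                config.env_means[ei]
                + g[l]
                + gxe.loc[l, env]
                + func.loc[l, env]
                + resid_sd * rng_design.standard_normal()
            )
            rows.append(
                {"environment": env, "genotype": l, "yield": yv}
            )
            band_rows.append(curve_lookup[(env, l)])
    table = pd.DataFrame(rows)
    B = np.asarray(band_rows)
    noise = config.band_noise_sd / np.sqrt(config.reps)
    for tp in range(1, config.n_timepoints + 1):
        obs = B + noise * rng_design.standard_normal(B.shape)
        cols = [f"band_{wl[j]:.0f}_t{tp}" for j in range(len(wl))]
        table = pd.concat(
            [table, pd.DataFrame(obs, columns=cols, index=table.index)], axis=1
        )
    table["weight_yield"] = config.reps / config.sigma2_error
    truth = GroundTruth(
        env_means=np.asarray(config.env_means[: config.n_envs]),
        line_effects=g,
        gxe_effects=gxe,
        beta1_grid=beta1,
        beta2_grid=pd.DataFrame(beta2, index=wl, columns=envs),
        functional_part=func,
        wavelengths=wl,
    )
    return table, truth


def simulate_experiment(config: SimConfig, use_identity_kinship: bool = False):
    """Full generator: pedigree + markers + kinship + curves + trial."""
    from . import kinship as km

    pedigree, markers = simulate_pedigree_markers(config)
    if use_identity_kinship:
        kin = km.identity_kinship(markers.line_ids)
    else:
        kin = km.genomic_relationship(km.qc_markers(markers))
    curves = simulate_curves(config, kin)
    table, truth = simulate_trial(config, kin, curves)
    return pedigree, markers, kin, curves, table, truth
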