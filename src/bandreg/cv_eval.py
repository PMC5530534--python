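"""Cross-validation schemes and per-environment prediction accuracy.

Two partition schemes over the (environment, genotype) cells:

* 50CV — per partition and per environment, half of the lines are
  assigned to training; every tested line must remain observed in at
  least one environment (predicting lines that are phenotyped somewhere).
* 90CV — one focal environment keeps only 10% of its lines in training
  (the remaining 90% are predicted); the other environments are fully
  observed.

Accuracy is the Pearson correlation between predicted and observed
second-stage yield values over the test cells of each environment; the
average over partitions (APC) and its standard error sd/sqrt(n) are
reported.  The identical partitions are reused across all models so that
comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayes_sampler, model_catalog

__all__ = [
    "CVPartition",
    "CVResult",
    "make_50cv",
    "make_90cv",
    "evaluate",
    "accuracy_from_predictions",
]


@dataclass
class CVPartition:
    """A train/test split of (environment, genotype) cells."""

    train: set[tuple[str, str]]
    test: set[tuple[str, str]]
    scheme: str
    seed: int
    focal_env: str | None = None

    def row_masks(self, cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Boolean train/test masks over the rows of a cells frame."""
        pairs = list(zip(cells["environment"], cells["genotype"]))
        tr = np.array([p in self.train for p in pairs])
        te = np.array([p in self.test for p in pairs])
        if not np.all(tr | te):
            missing = [p for p, a, b in zip(pairs, tr, te) if not (a or b)][:3]
            raise ValueError(f"cells not covered by the partition: {missing}")
        return tr, te


@dataclass
class CVResult:
    """Per-partition correlations and their per-environment summary."""

    per_partition: pd.DataFrame  # model, mode, env, partition, corr
    labels: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        def agg(s: pd.Series) -> pd.Series:
            vals = s.dropna().to_numpy()
            n = len(vals)
            return pd.Series(
                {
                    "apc": np.mean(vals) if n else np.nan,
                    "se": np.std(vals, ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                    "n_partitions": n,
                }
            )

        out = (
            self.per_partition.groupby(["model", "mode", "environment"])["corr"]
            .apply(agg)
            .unstack()
            .reset_index()
        )
        return out


def make_50cv(
    lines, envs, n_partitions: int = 10, seed: int = 0
) -> list[CVPartition]:
    """Ten (by default) 50/50 line splits per environment.

    Half the lines of each environment (floor for odd counts) go to
    training, drawn independently per environment; a line that would end
    up unobserved in *every* environment is repaired by swapping it into
    training in one uniformly chosen environment, in exchange for a line
    that stays observed elsewhere.
    """
    lines = list(lines)
    envs = list(envs)
    if len(envs) < 2:
        raise ValueError("50CV needs at least 2 environments to satisfy the "
                         "'observed somewhere' constraint")
    rng = np.random.default_rng(seed)
    n_train = len(lines) // 2
    partitions = []
    for _ in range(n_partitions):
        train_lines = {
            e: set(rng.choice(lines, size=n_train, replace=False)) for e in envs
        }
        # repair: every line must be in training in at least one environment
        for line in lines:
            if not any(line in train_lines[e] for e in envs):
                e = envs[rng.integers(len(envs))]
                candidates = [
                    m
                    for m in sorted(train_lines[e])
                    if any(m in train_lines[f] for f in envs if f != e)
                ]
                out = candidates[rng.integers(len(candidates))]
                train_lines[e].discard(out)
                train_lines[e].add(line)
        train = {(e, l) for e in envs for l in lines if l in train_lines[e]}
        test = {(e, l) for e in envs for l in lines if l not in train_lines[e]}
        partitions.append(CVPartition(train, test, scheme="50CV", seed=seed))
    return partitions


def make_90cv(
    lines, envs, focal_env: str, n_partitions: int = 10, seed: int = 0
) -> list[CVPartition]:
    """Splits that blank 90% of the lines of one focal environment.

    ``floor(0.10 * n_lines)`` lines of the focal environment are kept in
    training; all cells of the other environments are training.
    """
    lines = list(lines)
    envs = list(envs)
    if len(envs) < 2:
        raise ValueError("90CV needs at least 2 environments")
    if focal_env not in envs:
        raise ValueError(f"unknown focal environment {focal_env!r}")
    rng = np.random.default_rng(seed)
    n_keep = int(np.floor(0.10 * len(lines)))
    partitions = []
    for _ in range(n_partitions):
        keep = set(rng.choice(lines, size=n_keep, replace=False))
        train = {(e, l) for e in envs for l in lines if e != focal_env or l in keep}
        test = {(focal_env, l) for l in lines if l not in keep}
        partitions.append(
            CVPartition(train, test, scheme="90CV", seed=seed, focal_env=focal_env)
        )
    return partitions


def accuracy_from_predictions(
    cells: pd.DataFrame,
    observed: np.ndarray,
    predicted: np.ndarray,
    test_mask: np.ndarray,
    min_cells: int = 3,
) -> dict[str, float]:
    """Per-environment Pearson correlation over test cells."""
    out = {}
    for env in sorted(cells["environment"].unique()):
        m = test_mask & (cells["environment"] == env).to_numpy()
        if m.sum() < min_cells:
            out[env] = np.nan
            continue
        out[env] = float(np.corrcoef(observed[m], predicted[m])[0, 1])
    return out


def evaluate(
    partitions: list[CVPartition],
    model_specs: list[model_catalog.ModelSpec],
    table: pd.DataFrame,
    kinships=None,
    sampler_config: bayes_sampler.SamplerConfig | None = None,
    priors: bayes_sampler.PriorConfig | None = None,
    timepoint: int | None = None,
    yield_trait: str = "yield",
) -> CVResult:
    """Fit every model on every partition and summarize accuracies.

    Each model is compiled once against the full table; partitions only
    change the training-row subset, so all models see the identical
    splits (paired comparisons).  Sampler seeds are derived from the
    configured seed, the partition index and the model index so that
    every fit has its own reproducible stream.
    """
    sampler_config = sampler_config or bayes_sampler.SamplerConfig()
    bundles = [
        model_catalog.compile(
            spec, table, kinships=kinships, timepoint=timepoint, yield_trait=yield_trait
        )
        for spec in model_specs
    ]
    rows = []
    for ip, part in enumerate(partitions):
        for im, (spec, bundle) in enumerate(zip(model_specs, bundles)):
            tr, te = part.row_masks(bundle.cells)
            cfg = bayes_sampler.SamplerConfig(
                iterations=sampler_config.iterations,
                burn_in=sampler_config.burn_in,
                thin=sampler_config.thin,
                seed=(sampler_config.seed * 1_000_003 + ip * 131 + im) % (2**31 - 1),
            )
            fit = bayes_sampler.gibbs_fit(
                bundle, cfg, priors=priors, train_rows=np.where(tr)[0]
            )
            pred = bayes_sampler.predict(fit)
            accs = accuracy_from_predictions(bundle.cells, bundle.y, pred, te)
            for env, r in accs.items():
                rows.append(
                    {
                        "model": spec.model_id,
                        "mode": spec.relationship_mode,
                        "environment": env,
                        "partition": ip,
                        "corr": r,
                    }
                )
    return CVResult(per_partition=pd.DataFrame(rows))
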