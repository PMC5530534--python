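"""Relationship matrices and interaction covariances.

Line effects in the prediction models borrow information through a
relationship kernel: the genomic matrix ``G = WW'/m`` built from marker
dosages, the pedigree additive (numerator) relationship matrix ``A``
(twice the coefficient-of-parentage matrix), or the identity when neither
markers nor pedigree are used.  Genotype-by-environment effects use the
Kronecker covariance ``(K ⊗ I)σ²``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "Pedigree",
    "Kinship",
    "InteractionCov",
    "qc_markers",
    "genomic_relationship",
    "pedigree_A",
    "identity_kinship",
    "interaction_cov",
    "ensure_pd",
]


@dataclass
class MarkerMatrix:
    """Line × marker dosage matrix, entries in {0, 1, 2} or NaN."""

    dosages: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line_ids must be unique")
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("dosage shape does not match id lists")


@dataclass
class Pedigree:
    """Pedigree records (id, sire, dam); unknown parents are None."""

    records: list[tuple[str, str | None, str | None]]

    def parent_map(self) -> dict[str, tuple[str | None, str | None]]:
        return {i: (s, d) for i, s, d in self.records}

    def topological_order(self) -> list[str]:
        """Order with parents before offspring; rejects ancestry cycles."""
        parents = self.parent_map()
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(node: str, stack: list[str]) -> None:
            if node not in parents:
                return  # founder referenced only as a parent
            if state.get(node) == 1:
                return
            if state.get(node) == 0:
                cycle = stack[stack.index(node):] + [node]
                raise ValueError(f"pedigree cycle detected: {' -> '.join(cycle)}")
            state[node] = 0
            stack.append(node)
            for p in parents[node]:
                if p is not None:
                    visit(p, stack)
            stack.pop()
            state[node] = 1
            order.append(node)

        for ind in parents:
            visit(ind, [])
        return order


@dataclass
class Kinship:
    """Symmetric PSD relationship matrix with its line ordering."""

    values: np.ndarray
    line_ids: list[str]
    source: str  # genomic | pedigree | identity
    jitter: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match line_ids")

    def index_of(self, ids) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"line {e.args[0]!r} not in kinship") from None


@dataclass
class InteractionCov:
    """G×E covariance structure: effects over (line, env) cells.

    The stacked interaction effects, ordered line-major (all environments
    of line 1, then line 2, ...), have covariance ``(K ⊗ I_I)σ²``: the
    same line in two environments is uncorrelated, two lines in the same
    environment covary through the kinship.
    """

    kinship: Kinship
    n_envs: int
    cell_index: pd.DataFrame = field(repr=False)  # obs -> (line_idx, env_idx)

    def covariance(self, sigma2: float = 1.0) -> np.ndarray:
        """Observation-level covariance matrix (brute-force expansion)."""
        li = self.cell_index["line_idx"].to_numpy()
        ei = self.cell_index["env_idx"].to_numpy()
        K = self.kinship.values
        return sigma2 * K[np.ix_(li, li)] * (ei[:, None] == ei[None, :])


# ---------------------------------------------------------------------------
# marker QC and G


def qc_markers(
    raw: MarkerMatrix, max_missing: float = 0.30, min_maf: float = 0.05
) -> MarkerMatrix:
    """Quality-control marker dosages.

    Order of operations: (1) drop markers with more than ``max_missing``
    missing fraction, (2) impute remaining missing entries with the marker
    mean, (3) drop markers with minor allele frequency strictly below
    ``min_maf`` (computed from the imputed dosages).
    """
    X = raw.dosages.copy()
    finite = np.isfinite(X)
    if not np.all((X[finite] >= 0) & (X[finite] <= 2)):
        raise ValueError("dosages must lie in [0, 2] or be missing")

    miss_frac = 1.0 - finite.mean(axis=0)
    keep_miss = miss_frac <= max_missing
    X = X[:, keep_miss]
    ids = [m for m, k in zip(raw.marker_ids, keep_miss) if k]

    col_mean = np.nanmean(X, axis=0) if X.shape[1] else np.empty(0)
    nan_r, nan_c = np.where(~np.isfinite(X))
    X[nan_r, nan_c] = col_mean[nan_c]

    p = X.mean(axis=0) / 2.0 if X.shape[1] else np.empty(0)
    maf = np.minimum(p, 1.0 - p)
    keep_maf = maf >= min_maf  # rule is strictly "less than" for removal
    n_dropped_miss = int((~keep_miss).sum())
    n_dropped_maf = int((~keep_maf).sum())
    X = X[:, keep_maf]
    ids = [m for m, k in zip(ids, keep_maf) if k]
    if X.shape[1] == 0:
        raise ValueError(
            f"all markers removed by QC ({n_dropped_miss} by missingness, "
            f"{n_dropped_maf} by MAF)"
        )
    return MarkerMatrix(dosages=X, line_ids=list(raw.line_ids), marker_ids=ids)


def genomic_relationship(markers: MarkerMatrix, center: bool = True) -> Kinship:
    """Genomic relationship matrix ``G = WW'/m``.

    ``W`` is the dosage matrix column-centered by twice the allele
    frequency (VanRaden-style) unless ``center`` is False, in which case
    the raw dosages are used.
    """
    X = markers.dosages
    m = X.shape[1]
    if m == 0:
        raise ValueError("no markers")
    W = X - X.mean(axis=0) if center else X
    G = (W @ W.T) / m
    G = 0.5 * (G + G.T)
    return Kinship(values=G, line_ids=list(markers.line_ids), source="genomic")


# ---------------------------------------------------------------------------
# pedigree A


def pedigree_A(pedigree: Pedigree) -> Kinship:
    """Additive relationship matrix by the tabular method.

    ``a_jj = 1 + f_j`` with inbreeding ``f_j`` equal to half the
    relationship of the parents, and ``a_ij = (a_{i,sire(j)} +
    a_{i,dam(j)}) / 2`` for ``i`` preceding ``j``; equals twice the
    coefficient-of-parentage matrix.  Selfing is expressed by repeating
    the same parent id.
    """
    order = pedigree.topological_order()
    parents = pedigree.parent_map()
    idx = {ind: i for i, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for j, ind in enumerate(order):
        s, d = parents.get(ind, (None, None))
        si = idx.get(s) if s is not None else None
        di = idx.get(d) if d is not None else None
        if s is not None and si is None:
            raise ValueError(f"parent {s!r} of {ind!r} has no pedigree record")
        if d is not None and di is None:
            raise ValueError(f"parent {d!r} of {ind!r} has no pedigree record")
        for i in range(j):
            a_is = A[i, si] if si is not None else 0.0
            a_id = A[i, di] if di is not None else 0.0
            A[i, j] = A[j, i] = 0.5 * (a_is + a_id)
        A[j, j] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    return Kinship(values=A, line_ids=order, source="pedigree")


def identity_kinship(line_ids) -> Kinship:
    """Identity kernel: i.i.d. line effects (the no-marker/no-pedigree mode)."""
    ids = list(line_ids)
    return Kinship(values=np.eye(len(ids)), line_ids=ids, source="identity")


# ---------------------------------------------------------------------------
# interaction covariance and PD repair


def interaction_cov(kinship: Kinship, obs_map: pd.DataFrame) -> InteractionCov:
    """Covariance structure for genotype×environment interaction effects.

    ``obs_map`` has one row per observation with columns ``genotype`` and
    ``environment``; every genotype must be present in the kinship.
    """
    envs = sorted(obs_map["environment"].unique())
    env_idx = {e: i for i, e in enumerate(envs)}
    li = kinship.index_of(obs_map["genotype"])
    ei = obs_map["environment"].map(env_idx).to_numpy()
    cells = pd.DataFrame({"line_idx": li, "env_idx": ei})
    return InteractionCov(kinship=kinship, n_envs=len(envs), cell_index=cells)


def ensure_pd(
    kinship: Kinship, jitter: float | None = None, max_rel_jitter: float = 1e-2
) -> Kinship:
    """Add ``ε·I`` until a Cholesky factorization succeeds.

    The starting jitter defaults to ``1e-8 · trace/n``; it is multiplied
    by 10 until success, capped at ``max_rel_jitter · trace/n``.
    """
    K = kinship.values
    if not np.allclose(K, K.T, atol=1e-8 * max(1.0, np.abs(K).max())):
        raise ValueError("kinship matrix is not symmetric")
    scale = np.trace(K) / K.shape[0]
    eps = 0.0
    step = jitter if jitter is not None else 1e-8 * scale
    while True:
        try:
            np.linalg.cholesky(K + eps * np.eye(K.shape[0]))
            break
        except np.linalg.LinAlgError:
            eps = step if eps == 0.0 else eps * 10.0
            if eps > max_rel_jitter * scale:
                raise ValueError(
                    f"jitter {eps:.3g} exceeds cap {max_rel_jitter * scale:.3g}; "
                    "matrix is too far from positive definite"
                ) from None
    if eps == 0.0:
        return Kinship(K.copy(), list(kinship.line_ids), kinship.source, jitter=0.0)
    return Kinship(
        K + eps * np.eye(K.shape[0]), list(kinship.line_ids), kinship.source, jitter=eps
    )
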