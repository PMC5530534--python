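"""Truncated basis systems for functional covariates.

Hyperspectral reflectance curves observed on a dense wavelength grid are
projected onto a low-dimensional truncated basis (B-splines or Fourier).
The basis-coefficient representation turns the scalar-on-function
regression term ``∫ x(k) β(k) dk`` into an ordinary linear-model term
``x' d`` where the score vector ``x`` is obtained from the fitted curve
coefficients through the cross-product matrix ``J`` of the covariate and
coefficient bases.  Smoothness of the coefficient function is governed by
the penalty matrix ``P`` of second-derivative inner products, which enters
the model as a prior precision; designs can be whitened by ``P^{-1/2}`` so
that an i.i.d. normal prior on the whitened scale implies the smoothing
prior ``N(0, σ² P⁻¹)`` on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson
from scipy.interpolate import BSpline

__all__ = [
    "BasisSystem",
    "CurveSet",
    "CurveCoefficients",
    "PenaltyMatrix",
    "FunctionalDesign",
    "build_basis",
    "evaluate_basis",
    "fit_curve_coefficients",
    "cross_product_matrix",
    "penalty_matrix",
    "functional_design",
    "whiten_design",
]

#: number of quadrature points for the fixed-grid composite Simpson rule
QUADRATURE_POINTS = 4096


@dataclass(frozen=True)
class BasisSystem:
    """A truncated basis on a closed interval.

    Parameters
    ----------
    kind
        ``"bspline"`` or ``"fourier"``.
    domain
        Closed interval ``(a, b)`` in nm.
    size
        Number of basis functions.  For a Fourier basis this must be odd:
        one constant plus ``(size - 1) / 2`` sine/cosine pairs.
    order
        Spline order (degree + 1); B-splines only.  Default 4 (cubic).
    knots
        Full non-decreasing knot vector spanning the domain (B-splines
        only); built automatically with equally spaced interior knots.
    period
        Fundamental period of the Fourier basis; defaults to ``b - a``.
    """

    kind: str
    domain: tuple[float, float]
    size: int
    order: int | None = None
    knots: np.ndarray | None = field(default=None, repr=False)
    period: float | None = None

    @property
    def width(self) -> float:
        return self.domain[1] - self.domain[0]


@dataclass
class CurveSet:
    """Curves observed on a shared strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    values: np.ndarray  # n_curves x m
    curve_ids: list[tuple[str, str]] | None = None  # (environment, genotype)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValueError("wavelength grid must be 1-D with m >= 2")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"values have {self.values.shape[1]} columns but the grid "
                f"has {self.wavelengths.size} points"
            )


@dataclass
class CurveCoefficients:
    """Least-squares basis coefficients ĉ, one row per curve."""

    coef: np.ndarray  # n_curves x L
    basis: BasisSystem


@dataclass
class PenaltyMatrix:
    """Second-derivative roughness penalty ``P_ij = ∫ ψ″_i ψ″_j``."""

    values: np.ndarray  # S x S
    basis: BasisSystem


@dataclass
class FunctionalDesign:
    """Functional covariate scores ``x_ij``, one S-vector per curve."""

    scores: np.ndarray  # n_curves x S
    J: np.ndarray  # L x S cross-product matrix
    whitened: bool = False


# ---------------------------------------------------------------------------
# construction and evaluation


def build_basis(
    kind: str,
    domain: tuple[float, float],
    size: int,
    order: int = 4,
) -> BasisSystem:
    """Build a B-spline or Fourier basis on ``domain``.

    B-spline knots are equally spaced over the domain with full boundary
    multiplicity, so the number of basis functions equals the number of
    interior knots plus the order.  The Fourier basis is orthonormal:
    constant ``1/√T`` plus pairs ``√(2/T)·sin``, ``√(2/T)·cos`` of the
    harmonics of the fundamental period ``T = b − a``.
    """
    a, b = float(domain[0]), float(domain[1])
    if not b > a:
        raise ValueError(f"domain [{a}, {b}] is empty")
    if size < 1:
        raise ValueError("basis size must be >= 1")
    if kind == "bspline":
        if order < 1:
            raise ValueError("spline order must be >= 1")
        if size < order:
            raise ValueError(
                f"B-spline basis needs size >= order (got size={size}, order={order})"
            )
        n_interior = size - order
        interior = np.linspace(a, b, n_interior + 2)[1:-1]
        knots = np.concatenate([np.full(order, a), interior, np.full(order, b)])
        return BasisSystem("bspline", (a, b), size, order=order, knots=knots)
    if kind == "fourier":
        if size != 1 and size % 2 == 0:
            raise ValueError(
                f"Fourier basis size must be odd (constant + sin/cos pairs); got {size}"
            )
        return BasisSystem("fourier", (a, b), size, period=b - a)
    raise ValueError(f"unknown basis kind {kind!r}")


def _check_points(basis: BasisSystem, points: np.ndarray) -> np.ndarray:
    a, b = basis.domain
    pts = np.asarray(points, dtype=float)
    tol = 1e-8 * max(1.0, abs(a), abs(b))
    bad = (pts < a - tol) | (pts > b + tol)
    if np.any(bad):
        raise ValueError(
            f"evaluation point {pts[bad][0]} outside basis domain [{a}, {b}]"
        )
    return np.clip(pts, a, b)


def evaluate_basis(
    basis: BasisSystem, points: np.ndarray, deriv: int = 0
) -> np.ndarray:
    """Evaluate all basis functions (or a derivative) at ``points``.

    Returns the m × L matrix ``Φ`` with ``Φ[r, l] = φ_l(k_r)``.
    """
    pts = _check_points(basis, points)
    if basis.kind == "bspline":
        k = basis.order - 1
        if deriv == 0:
            return BSpline.design_matrix(
                pts, basis.knots, k, extrapolate=False
            ).toarray()
        if deriv > k:
            return np.zeros((pts.size, basis.size))
        out = np.empty((pts.size, basis.size))
        for l in range(basis.size):
            c = np.zeros(basis.size)
            c[l] = 1.0
            spl = BSpline(basis.knots, c, k, extrapolate=False).derivative(deriv)
            out[:, l] = spl(pts)
        return np.nan_to_num(out)
    # Fourier: constant + sin/cos pairs, orthonormal over one period
    T = basis.period
    a = basis.domain[0]
    omega = 2.0 * np.pi / T
    out = np.empty((pts.size, basis.size))
    if deriv == 0:
        out[:, 0] = 1.0 / np.sqrt(T)
    else:
        out[:, 0] = 0.0
    amp = np.sqrt(2.0 / T)
    for pair in range((basis.size - 1) // 2):
        h = pair + 1
        w = h * omega
        arg = w * (pts - a)
        # d/dk cycles sin -> cos -> -sin -> -cos with a factor w each time
        sin_d = amp * w**deriv * np.sin(arg + deriv * np.pi / 2.0)
        cos_d = amp * w**deriv * np.cos(arg + deriv * np.pi / 2.0)
        out[:, 1 + 2 * pair] = sin_d
        out[:, 2 + 2 * pair] = cos_d
    return out


# ---------------------------------------------------------------------------
# curve fitting and functional design


def fit_curve_coefficients(curves: CurveSet, basis: BasisSystem) -> CurveCoefficients:
    """Ordinary least-squares projection of each curve onto the basis.

    Solves the normal equations ``ĉ = (Φ'Φ)⁻¹ Φ' x`` per curve; rejects a
    grid that does not resolve the basis (rank-deficient ``Φ'Φ``).
    """
    phi = evaluate_basis(basis, curves.wavelengths)
    gram = phi.T @ phi
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"basis of size {basis.size} is not resolved by the "
            f"{curves.wavelengths.size}-point grid (cond(Φ'Φ) = {cond:.3g})"
        )
    coef = np.linalg.solve(gram, phi.T @ curves.values.T).T
    return CurveCoefficients(coef=coef, basis=basis)


def _quad_grid(domain: tuple[float, float]) -> np.ndarray:
    return np.linspace(domain[0], domain[1], QUADRATURE_POINTS)


def cross_product_matrix(
    covariate_basis: BasisSystem, coefficient_basis: BasisSystem
) -> np.ndarray:
    """Cross-product matrix ``J[l, s] = ∫ φ_l(k) ψ_s(k) dk``.

    Both bases must share the integration domain; the integrals use the
    module-standard fixed-grid composite Simpson rule.
    """
    if covariate_basis.domain != coefficient_basis.domain:
        raise ValueError(
            f"mismatched domains {covariate_basis.domain} vs {coefficient_basis.domain}"
        )
    grid = _quad_grid(covariate_basis.domain)
    phi = evaluate_basis(covariate_basis, grid)  # m x L
    psi = evaluate_basis(coefficient_basis, grid)  # m x S
    J = np.empty((covariate_basis.size, coefficient_basis.size))
    for s in range(coefficient_basis.size):
        J[:, s] = simpson(phi * psi[:, s : s + 1], x=grid, axis=0)
    return J


def penalty_matrix(basis: BasisSystem) -> PenaltyMatrix:
    """Roughness penalty ``P_ij = ∫ ψ″_i(t) ψ″_j(t) dt`` over the domain.

    For the Fourier basis the constant function has a vanishing second
    derivative, which would give the corresponding coefficient a prior
    degenerate at zero; entry (1, 1) is therefore overwritten to 1.
    """
    if basis.kind == "bspline" and basis.order <= 2:
        # piecewise-linear or constant splines: second derivative vanishes
        P = np.zeros((basis.size, basis.size))
        return PenaltyMatrix(values=P, basis=basis)
    grid = _quad_grid(basis.domain)
    d2 = evaluate_basis(basis, grid, deriv=2)
    P = np.empty((basis.size, basis.size))
    for j in range(basis.size):
        P[:, j] = simpson(d2 * d2[:, j : j + 1], x=grid, axis=0)
    P = 0.5 * (P + P.T)
    if basis.kind == "fourier":
        P[0, 0] = 1.0
    return PenaltyMatrix(values=P, basis=basis)


def functional_design(curve_coefs: CurveCoefficients, J: np.ndarray) -> FunctionalDesign:
    """Scores ``x_ij = J' ĉ_ij`` stacked row-per-curve (n × S)."""
    J = np.asarray(J, dtype=float)
    if curve_coefs.coef.shape[1] != J.shape[0]:
        raise ValueError(
            f"coefficient dimension {curve_coefs.coef.shape[1]} does not match "
            f"J row dimension {J.shape[0]}"
        )
    return FunctionalDesign(scores=curve_coefs.coef @ J, J=J, whitened=False)


def matrix_inv_sqrt(P: np.ndarray, null_reg: float = 1e-5) -> np.ndarray:
    """Symmetric ``P^{-1/2}`` with a regularized null space.

    A second-derivative penalty is singular on its polynomial null space
    (constants, and straight lines for splines of order ≥ 3); those
    directions carry no roughness and should remain in the model nearly
    unpenalized, as in smoothing splines.  Eigenvalues below
    ``null_reg · λ_max`` are therefore floored at that value rather than
    pseudo-inverted away, which leaves the null directions present with
    the mildest penalty in the spectrum.
    """
    P = np.asarray(P, dtype=float)
    if not np.allclose(P, P.T, atol=1e-8 * max(1.0, np.abs(P).max())):
        raise ValueError("penalty matrix is not symmetric")
    w, V = np.linalg.eigh(P)
    wmax = max(w.max(), 0.0)
    if wmax == 0.0:
        raise ValueError("penalty matrix is identically zero")
    w_eff = np.maximum(w, null_reg * wmax)
    return (V / np.sqrt(w_eff)) @ V.T


def whiten_design(design: FunctionalDesign, penalty: PenaltyMatrix) -> FunctionalDesign:
    """Post-multiply the scores by the symmetric square root of ``P⁻¹``.

    On the whitened scale an i.i.d. ``N(0, σ²)`` prior on the coefficients
    implies ``N(0, σ² P⁻¹)`` on the original scale.  A degenerate all-zero
    penalty (e.g. from a piecewise-linear spline basis) carries no
    smoothness information; whitening then falls back to the identity with
    a warning.
    """
    P = penalty.values
    if not np.allclose(P, P.T, atol=1e-8 * max(1.0, np.abs(P).max())):
        raise ValueError("penalty matrix is not symmetric")
    if np.abs(P).max() <= 1e-12:
        warnings.warn(
            "penalty matrix is identically zero; whitening degenerates and the "
            "identity is used instead",
            RuntimeWarning,
            stacklevel=2,
        )
        return FunctionalDesign(scores=design.scores.copy(), J=design.J, whitened=True)
    W = matrix_inv_sqrt(P)
    return FunctionalDesign(scores=design.scores @ W, J=design.J, whitened=True)
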