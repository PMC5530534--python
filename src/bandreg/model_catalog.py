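"""The catalog of 14 second-stage prediction models.

Every model regresses the yield BLUE of an (environment, genotype) cell
on environment main effects plus some combination of: a line effect with
a relationship kernel (genomic G, pedigree A, or identity), a
genotype-by-environment interaction with Kronecker covariance (K ⊗ I),
and reflectance-band terms — either the 250 raw band covariates
("conventional") or their low-dimensional functional-basis scores
("functional"), each optionally with band-by-environment interaction
(an extra environment-specific copy of the band block).

    M1  : E + g                          M2  : M1 + gE
    M3  : M1 + bands                     M4  : M2 + bands
    M5/6: M1 + functional (bspl/four)    M7/8: M2 + functional
    M9  : M3 + band×env                  M10 : M4 + band×env
    M11/12: M5/6 + functional band×env   M13/14: M7/8 + functional band×env

Each model runs in one of three relationship modes: WG (genomic kernel),
WA (pedigree kernel) or WO (identity, i.i.d. line effects).

Kernel random blocks are compiled in the eigenbasis of their kernel:
with K = V Λ V', the design Z·V·Λ^{1/2} with i.i.d. N(0, σ²) coefficients
has exactly the covariance Z K Z' σ², so the sampler treats every block
as a ridge block with its own variance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fda_basis
from .kinship import Kinship

__all__ = [
    "ModelSpec",
    "DesignBlock",
    "DesignBundle",
    "MODEL_IDS",
    "BXE_PAIRS",
    "compile",
    "spec_pairs",
    "parse_band_columns",
]

# model_id -> (has_gE, band_mode, has_bandxenv, default_basis)
# band_mode: None (no bands), "conventional", "functional"
_MODEL_TABLE: dict[str, tuple[bool, str | None, bool, str | None]] = {
    "M1": (False, None, False, None),
    "M2": (True, None, False, None),
    "M3": (False, "conventional", False, None),
    "M4": (True, "conventional", False, None),
    "M5": (False, "functional", False, "bspline"),
    "M6": (False, "functional", False, "fourier"),
    "M7": (True, "functional", False, "bspline"),
    "M8": (True, "functional", False, "fourier"),
    "M9": (False, "conventional", True, None),
    "M10": (True, "conventional", True, None),
    "M11": (False, "functional", True, "bspline"),
    "M12": (False, "functional", True, "fourier"),
    "M13": (True, "functional", True, "bspline"),
    "M14": (True, "functional", True, "fourier"),
}

MODEL_IDS = tuple(_MODEL_TABLE)

#: band×env model -> its counterpart without the band×env term
BXE_PAIRS = {
    "M9": "M3",
    "M10": "M4",
    "M11": "M5",
    "M12": "M6",
    "M13": "M7",
    "M14": "M8",
}


@dataclass(frozen=True)
class ModelSpec:
    """One of M1–M14 with a relationship mode and basis settings."""

    model_id: str
    relationship_mode: str = "WG"
    basis_kind: str | None = None
    L: int = 21
    S: int = 21
    standardize_bands: bool = True
    use_penalty: bool = True  # False: identity in place of the penalty P
    use_weights: bool = True

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_TABLE:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if self.relationship_mode not in ("WG", "WA", "WO"):
            raise ValueError(f"unknown relationship mode {self.relationship_mode!r}")
        has_gE, band_mode, _, default_basis = _MODEL_TABLE[self.model_id]
        if band_mode == "functional" and self.basis_kind is None:
            object.__setattr__(self, "basis_kind", default_basis)

    @property
    def has_gE(self) -> bool:
        return _MODEL_TABLE[self.model_id][0]

    @property
    def band_mode(self) -> str | None:
        return _MODEL_TABLE[self.model_id][1]

    @property
    def has_bandxenv(self) -> bool:
        return _MODEL_TABLE[self.model_id][2]


@dataclass
class DesignBlock:
    """A dense design block with a shared prior.

    ``prior`` is ``"fixed"`` (normal with large fixed variance) or
    ``"random"`` (normal with a variance updated from its scaled-inv-χ²
    full conditional).
    """

    name: str
    X: np.ndarray
    prior: str = "random"


@dataclass
class DesignBundle:
    """Compiled response + design blocks for one model on one table."""

    y: np.ndarray
    blocks: list[DesignBlock]
    cells: pd.DataFrame  # environment, genotype per row
    envs: list[str]
    spec: ModelSpec
    weights: np.ndarray | None = None
    artifacts: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def design_matrix(self) -> np.ndarray:
        return np.hstack([b.X for b in self.blocks])


def spec_pairs() -> dict[str, tuple[str, ...]]:
    """Map each conventional model to its functional counterparts.

    The B-spline counterpart comes first, the Fourier one second; the
    no-band models M1 and M2 map to an empty tuple.
    """
    return {
        "M1": (),
        "M2": (),
        "M3": ("M5", "M6"),
        "M4": ("M7", "M8"),
        "M9": ("M11", "M12"),
        "M10": ("M13", "M14"),
    }


_BAND_RE = re.compile(r"^band_(\d+(?:\.\d+)?)_t(\d+)$")


def parse_band_columns(columns) -> pd.DataFrame:
    """Parse ``band_<wavelength>_t<timepoint>`` column names.

    Returns a frame with columns (name, wavelength, timepoint) sorted
    wavelength-major within time-point.
    """
    rows = []
    for c in columns:
        m = _BAND_RE.match(c)
        if m:
            rows.append({"name": c, "wavelength": float(m.group(1)),
                         "timepoint": int(m.group(2))})
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["timepoint", "wavelength"]).reset_index(drop=True)
    return out


def _kernel_columns(kinship: Kinship, genotypes: pd.Series) -> np.ndarray:
    """Eigen-transformed kernel design: Z V Λ^{1/2} with PSD clipping."""
    w, V = np.linalg.eigh(kinship.values)
    w = np.clip(w, 0.0, None)
    T = V * np.sqrt(w)
    rows = kinship.index_of(genotypes)
    return T[rows, :]


def _env_copies(X: np.ndarray, env_codes: np.ndarray, n_envs: int) -> np.ndarray:
    """Environment-specific copies: X masked to each environment's rows."""
    n, k = X.shape
    out = np.zeros((n, n_envs * k))
    for i in range(n_envs):
        mask = env_codes == i
        out[mask, i * k:(i + 1) * k] = X[mask]
    return out


def compile(
    spec: ModelSpec,
    table: pd.DataFrame,
    kinships: dict[str, Kinship] | None = None,
    timepoint: int | None = None,
    yield_trait: str = "yield",
    band_domain: tuple[float, float] | None = None,
) -> DesignBundle:
    """Compile a model spec against a second-stage table.

    ``table`` is the output of :func:`bandreg.stage_one.assemble_second_stage`.
    For models with band terms, ``timepoint`` selects which time-point's
    band columns enter (defaults to the only one present).  ``kinships``
    must provide key ``"G"`` for WG mode and ``"A"`` for WA mode.
    """
    envs = sorted(table["environment"].unique())
    env_code = {e: i for i, e in enumerate(envs)}
    ecodes = table["environment"].map(env_code).to_numpy()
    n = len(table)
    cells = table[["environment", "genotype"]].reset_index(drop=True)

    # relationship kernel
    mode = spec.relationship_mode
    if mode == "WO":
        lines = sorted(table["genotype"].unique())
        kin = Kinship(np.eye(len(lines)), lines, "identity")
    else:
        key = "G" if mode == "WG" else "A"
        if not kinships or key not in kinships:
            raise ValueError(f"mode {mode} requires kinship {key!r}")
        kin = kinships[key]
        kin.index_of(table["genotype"].unique())  # validate coverage

    blocks: list[DesignBlock] = []
    X_env = np.zeros((n, len(envs)))
    X_env[np.arange(n), ecodes] = 1.0
    blocks.append(DesignBlock("env", X_env, prior="fixed"))

    Xg = _kernel_columns(kin, table["genotype"])
    blocks.append(DesignBlock("g", Xg, prior="random"))
    if spec.has_gE:
        blocks.append(
            DesignBlock("gE", _env_copies(Xg, ecodes, len(envs)), prior="random")
        )

    artifacts: dict = {"envs": envs, "kinship_source": kin.source}

    if spec.band_mode is not None:
        info = parse_band_columns(table.columns)
        if info.empty:
            raise ValueError("model has band terms but the table has no band columns")
        tps = sorted(info["timepoint"].unique())
        tp = timepoint if timepoint is not None else tps[0]
        if tp not in tps:
            raise ValueError(f"timepoint {tp} not in table (has {tps})")
        sel = info[info["timepoint"] == tp]
        B = table[sel["name"].tolist()].to_numpy(dtype=float)
        wavelengths = sel["wavelength"].to_numpy()
        artifacts["timepoint"] = tp
        artifacts["wavelengths"] = wavelengths

        if spec.band_mode == "conventional":
            if spec.standardize_bands:
                mu, sd = B.mean(axis=0), B.std(axis=0)
                sd[sd == 0] = 1.0
                B = (B - mu) / sd
                artifacts["band_center"], artifacts["band_scale"] = mu, sd
            blocks.append(DesignBlock("bands", B, prior="random"))
            if spec.has_bandxenv:
                blocks.append(
                    DesignBlock(
                        "bands_env", _env_copies(B, ecodes, len(envs)), prior="random"
                    )
                )
        else:  # functional
            dom = band_domain or (wavelengths[0], wavelengths[-1])
            phi = fda_basis.build_basis(spec.basis_kind, dom, spec.L)
            psi = fda_basis.build_basis(spec.basis_kind, dom, spec.S)
            curves = fda_basis.CurveSet(wavelengths=wavelengths, values=B)
            coefs = fda_basis.fit_curve_coefficients(curves, phi)
            J = fda_basis.cross_product_matrix(phi, psi)
            design = fda_basis.functional_design(coefs, J)
            pen = fda_basis.penalty_matrix(psi)
            if spec.use_penalty:
                wdesign = fda_basis.whiten_design(design, pen)
                if np.abs(pen.values).max() <= 1e-12:
                    whitener = np.eye(spec.S)
                else:
                    whitener = fda_basis.matrix_inv_sqrt(pen.values)
            else:
                wdesign = fda_basis.FunctionalDesign(
                    scores=design.scores.copy(), J=J, whitened=True
                )
                whitener = np.eye(spec.S)
            artifacts.update(
                basis_phi=phi, basis_psi=psi, J=J, penalty=pen, whitener=whitener
            )
            blocks.append(DesignBlock("func", wdesign.scores, prior="random"))
            if spec.has_bandxenv:
                blocks.append(
                    DesignBlock(
                        "func_env",
                        _env_copies(wdesign.scores, ecodes, len(envs)),
                        prior="random",
                    )
                )

    y = table[yield_trait].to_numpy(dtype=float)
    weights = None
    if spec.use_weights and "weight_yield" in table.columns:
        weights = table["weight_yield"].to_numpy(dtype=float)
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")

    return DesignBundle(
        y=y, blocks=blocks, cells=cells, envs=envs, spec=spec,
        weights=weights, artifacts=artifacts,
    )
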