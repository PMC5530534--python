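"""Readers, writers, run configuration and the pipeline driver.

All interchange files are comma-delimited text: the plot-level trial
table (mandatory columns ``environment, trial, rep, block, genotype,
yield`` plus band columns ``band_<wavelength>_t<timepoint>``), the
line × marker dosage matrix (first column line id, ``NA`` for missing),
the 3-column pedigree (empty or ``0`` for unknown parents), square
kinship matrices with an id header, the second-stage table, and tidy
cross-validation results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes_sampler, cv_eval, kinship as km, model_catalog, stage_one
from . import synthetic_data

__all__ = [
    "read_plot_table",
    "write_table",
    "read_markers",
    "read_pedigree",
    "write_kinship",
    "read_kinship",
    "RunConfig",
    "run_pipeline",
]

MANDATORY_PLOT_COLUMNS = ["environment", "trial", "rep", "block", "genotype", "yield"]


def read_plot_table(path) -> pd.DataFrame:
    """Read and validate a plot-level trial table."""
    t = pd.read_csv(path)
    for c in MANDATORY_PLOT_COLUMNS:
        if c not in t.columns:
            raise ValueError(f"plot table {path} is missing column {c!r}")
    bands = stage_one.band_columns(t.columns)
    for c in ["yield"] + bands:
        vals = pd.to_numeric(t[c], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(f"non-numeric value in column {c!r}, row {row}")
        t[c] = vals
    return t


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_markers(path) -> km.MarkerMatrix:
    t = pd.read_csv(path, index_col=0, na_values=["NA", ""])
    return km.MarkerMatrix(
        dosages=t.to_numpy(dtype=float),
        line_ids=[str(i) for i in t.index],
        marker_ids=[str(c) for c in t.columns],
    )


def read_pedigree(path) -> km.Pedigree:
    t = pd.read_csv(path, dtype=str).fillna("")
    if t.shape[1] != 3:
        raise ValueError("pedigree file must have exactly 3 columns (id, sire, dam)")
    records = []
    for _, (i, s, d) in t.iterrows():
        records.append(
            (i, s if s not in ("", "0") else None, d if d not in ("", "0") else None)
        )
    return km.Pedigree(records=records)


def write_kinship(kin: km.Kinship, path) -> None:
    pd.DataFrame(kin.values, index=kin.line_ids, columns=kin.line_ids).to_csv(path)


def read_kinship(path, source: str = "genomic") -> km.Kinship:
    t = pd.read_csv(path, index_col=0)
    return km.Kinship(
        values=t.to_numpy(dtype=float), line_ids=[str(i) for i in t.index],
        source=source,
    )


# ---------------------------------------------------------------------------
# run configuration


_KNOWN_KEYS = {
    "paths": {"plots", "markers", "pedigree", "out_dir", "second_stage"},
    "model": {"id", "mode", "basis", "L", "S", "standardize_bands", "use_penalty",
              "use_weights", "timepoint"},
    "sampler": {"iterations", "burn_in", "thin"},
    "cv": {"scheme", "partitions", "focal_env"},
    "simulate": None,  # validated against SimConfig fields
    "seed": None,
}


@dataclass
class RunConfig:
    """Validated run configuration (see the example in the README)."""

    raw: dict
    path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(raw=raw, path=str(path))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key, val in self.raw.items():
            if key not in _KNOWN_KEYS:
                raise ValueError(f"unknown config key {key!r}")
            allowed = _KNOWN_KEYS[key]
            if allowed is not None and isinstance(val, dict):
                for sub in val:
                    if sub not in allowed:
                        raise ValueError(f"unknown config key {key}.{sub}")
        if "simulate" in self.raw and self.raw["simulate"]:
            valid = set(synthetic_data.SimConfig.__dataclass_fields__)
            for sub in self.raw["simulate"]:
                if sub not in valid:
                    raise ValueError(f"unknown config key simulate.{sub}")
        model = self.raw.get("model", {})
        paths = self.raw.get("paths", {})
        if model.get("mode") == "WA" and "pedigree" not in paths \
                and not self.raw.get("simulate"):
            raise ValueError("mode WA requires a pedigree file")
        if model.get("mode") == "WG" and "markers" not in paths \
                and not self.raw.get("simulate"):
            raise ValueError("mode WG requires a marker file")
        for name, p in paths.items():
            if name != "out_dir" and not Path(p).exists():
                raise ValueError(f"configured path {name}: {p} does not exist")

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def model_spec(self) -> model_catalog.ModelSpec:
        m = self.raw.get("model", {})
        return model_catalog.ModelSpec(
            model_id=m.get("id", "M1"),
            relationship_mode=m.get("mode", "WO"),
            basis_kind=m.get("basis"),
            L=int(m.get("L", 21)),
            S=int(m.get("S", 21)),
            standardize_bands=bool(m.get("standardize_bands", True)),
            use_penalty=bool(m.get("use_penalty", True)),
            use_weights=bool(m.get("use_weights", True)),
        )

    def sampler_config(self) -> bayes_sampler.SamplerConfig:
        s = self.raw.get("sampler", {})
        return bayes_sampler.SamplerConfig(
            iterations=int(s.get("iterations", 30_000)),
            burn_in=int(s.get("burn_in", 20_000)),
            thin=int(s.get("thin", 1)),
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# pipeline driver


def _stage_one_all(plots: pd.DataFrame) -> pd.DataFrame:
    traits = ["yield"] + stage_one.band_columns(plots.columns)
    checks = {g for g in plots["genotype"].unique() if str(g).startswith("CHK")}
    results = {}
    for env, env_table in plots.groupby("environment"):
        results[env] = stage_one.adjust_environment(env_table, traits)
    return stage_one.assemble_second_stage(results, drop_genotypes=checks)


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute simulate (optional) → stage one → compile → fit or cv.

    Writes the second-stage table, posterior/CV summaries and a
    provenance log into the output directory; returns the paths.
    """
    paths = config.raw.get("paths", {})
    out = Path(out_dir or paths.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def _fail(stage: str, err: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    kinships: dict[str, km.Kinship] = {}
    try:
        if config.raw.get("simulate"):
            sim = synthetic_data.SimConfig(
                **{**config.raw["simulate"], "seed": config.seed}
            )
            pedigree, markers, kin, curves, plots, _ = (
                synthetic_data.simulate_experiment(sim)
            )
            kinships["G"] = kin
            kinships["A"] = km.pedigree_A(pedigree)
            write_table(plots, out / "plots.csv")
            written["plots"] = str(out / "plots.csv")
        else:
            plots = read_plot_table(paths["plots"])
            if "markers" in paths:
                kinships["G"] = km.genomic_relationship(
                    km.qc_markers(read_markers(paths["markers"]))
                )
            if "pedigree" in paths:
                kinships["A"] = km.pedigree_A(read_pedigree(paths["pedigree"]))
    except RuntimeError:
        raise
    except Exception as e:  # noqa: BLE001 - report the failing stage
        _fail("simulate/load", e)

    try:
        if "second_stage" in paths:
            table = pd.read_csv(paths["second_stage"])
        else:
            table = _stage_one_all(plots)
        write_table(table, out / "second_stage.csv")
        written["second_stage"] = str(out / "second_stage.csv")
    except Exception as e:  # noqa: BLE001
        _fail("stage1", e)

    spec = config.model_spec()
    sampler_cfg = config.sampler_config()
    tp = config.raw.get("model", {}).get("timepoint")
    cv_cfg = config.raw.get("cv")
    try:
        if cv_cfg:
            lines = sorted(table["genotype"].unique())
            envs = sorted(table["environment"].unique())
            n_part = int(cv_cfg.get("partitions", 10))
            if str(cv_cfg.get("scheme", "50")) in ("50", "50CV"):
                parts = cv_eval.make_50cv(lines, envs, n_part, seed=config.seed)
            else:
                parts = cv_eval.make_90cv(
                    lines, envs, cv_cfg["focal_env"], n_part, seed=config.seed
                )
            specs = [spec]
            res = cv_eval.evaluate(
                parts, specs, table, kinships=kinships,
                sampler_config=sampler_cfg, timepoint=tp,
            )
            res.summary().to_csv(out / "cv_result.csv", index=False)
            written["cv_result"] = str(out / "cv_result.csv")
        else:
            bundle = model_catalog.compile(spec, table, kinships=kinships, timepoint=tp)
            fit = bayes_sampler.gibbs_fit(bundle, sampler_cfg)
            summ = pd.DataFrame(
                {
                    "block": np.repeat(
                        [b.name for b in bundle.blocks],
                        [b.X.shape[1] for b in bundle.blocks],
                    ),
                    "posterior_mean": fit.coef_mean,
                    "posterior_sd": fit.coef_sd,
                }
            )
            summ.to_csv(out / "fit_summary.csv", index=False)
            written["fit_summary"] = str(out / "fit_summary.csv")
            chains = pd.DataFrame(fit.variance_chains)
            chains.to_csv(out / "variance_chains.csv", index=False)
            written["variance_chains"] = str(out / "variance_chains.csv")
    except Exception as e:  # noqa: BLE001
        _fail("fit/cv", e)

    from . import __version__

    log = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "outputs": written,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    written["provenance"] = str(out / "provenance.json")
    return written
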