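import numpy as np
import pytest

from bandreg import kinship as km
from bandreg import synthetic_data as sd


@pytest.fixture(scope="session")
def tiny_cfg():
    return sd.default_config(
        n_lines=60, trials=2, n_bands=20, n_markers=300, seed=3
    )


@pytest.fixture(scope="session")
def tiny_experiment(tiny_cfg):
    """A small but complete plot-level experiment with ground truth."""
    pedigree, markers = sd.simulate_pedigree_markers(tiny_cfg)
    kin = km.genomic_relationship(km.qc_markers(markers))
    curves = sd.simulate_curves(tiny_cfg, kin)
    table, truth = sd.simulate_trial(tiny_cfg, kin, curves)
    return {
        "config": tiny_cfg,
        "pedigree": pedigree,
        "markers": markers,
        "kinship": kin,
        "curves": curves,
        "table": table,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def desk_cells():
    """Default desk-scale experiment simulated at the cell (BLUE) level."""
    cfg = sd.default_config(seed=7)
    _, markers = sd.simulate_pedigree_markers(cfg)
    kin = km.genomic_relationship(km.qc_markers(markers))
    table, truth = sd.simulate_second_stage_table(cfg, kin)
    return {"config": cfg, "kinship": kin, "table": table, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
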