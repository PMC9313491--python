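"""Shared fixtures: desk-scale synthetic experiments generated once."""

import numpy as np
import pandas as pd
import pytest

from pvn.containers import CountMatrix
from pvn.simulate import SimConfig, generate_experiment, reference_tables


def small_config(seed: int = 7, **kwargs) -> SimConfig:
    """A scaled-down study: same structure, fewer cells and genes."""
    defaults = dict(
        n_cells_tri={"EC": 180, "astrocyte": 80, "GSC": 60},
        n_cells_mono={"EC": 200, "astrocyte": 50, "GSC": 80},
        n_genes=600,
        n_signature_genes=30,
        seed=seed,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_experiment():
    cfg = small_config()
    mono, tri, gt = generate_experiment(cfg)
    lr, secreted, gmt = reference_tables(cfg, gt)
    return {
        "cfg": cfg, "mono": mono, "tri": tri, "gt": gt,
        "lr": lr, "secreted": secreted, "gmt": gmt,
    }


def make_count_matrix(counts, genes=None, cells=None, condition="mono"):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{j}" for j in range(counts.shape[1])]
    meta = pd.DataFrame({"condition": condition}, index=pd.Index(cells))
    return CountMatrix(counts, pd.Index(genes), pd.Index(cells), meta)
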