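import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import striaging as st


def make_count_matrix(counts: np.ndarray, prefix: str = "c") -> st.CountMatrix:
    counts = np.asarray(counts)
    return st.CountMatrix(
        sp.csr_matrix(counts),
        pd.Index([f"{prefix}{i}" for i in range(counts.shape[0])]),
        pd.Index([f"g{j}" for j in range(counts.shape[1])]),
    )


@pytest.fixture(scope="session")
def sim_default():
    """Default two-age dataset: 7 subtypes, aging effects planted."""
    cfg = st.SimulationConfig(seed=11, n_cells_per_age=400, n_genes=250)
    cells, counts, truth = st.simulate_dataset(cfg)
    return cfg, cells, counts, truth


@pytest.fixture(scope="session")
def sim_default_norm(sim_default):
    _, _, counts, _ = sim_default
    return st.normalize_log(counts)


@pytest.fixture(scope="session")
def sep3():
    """Three well-separated, equally spatially distributed subtypes."""
    cfg = st.SimulationConfig(
        seed=2,
        n_cells_per_age=750,
        n_genes=120,
        n_subtypes=3,
        marker_log2fc=3.0,
        subtype_props_young=np.array([0.5, 0.3, 0.2]),
        subtype_props_aged=np.array([0.5, 0.3, 0.2]),
    )
    cells, counts, truth = st.simulate_dataset(cfg)
    return cfg, cells, counts, truth


@pytest.fixture(scope="session")
def sep3_norm(sep3):
    _, _, counts, _ = sep3
    return st.normalize_log(counts)
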