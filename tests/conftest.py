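import numpy as np
import pandas as pd
import pytest

import prosubtype as ps


@pytest.fixture(scope="session")
def small_expr() -> ps.ExpressionMatrix:
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.lognormal(1.0, 1.0, size=(20, 8)),
        index=[f"G{i:02d}" for i in range(20)],
        columns=[f"S{i}" for i in range(8)],
    )
    return ps.ExpressionMatrix(data)


@pytest.fixture(scope="session")
def cluster_signature() -> ps.SignatureMatrix:
    return ps.simulate_cluster_profiles(n_genes=300, n_clusters=4, seed=11)


@pytest.fixture(scope="session")
def mixtures(cluster_signature):
    cfg = ps.SimulationConfig(seed=11, n_genes=300, n_bulk_samples=60, noise_cv=0.1)
    return ps.simulate_bulk_mixtures(cluster_signature, cfg)


@pytest.fixture(scope="session")
def reference_sim():
    """Small labeled single-cell + sorted-bulk reference with planted markers."""
    cfg = ps.SimulationConfig(
        seed=5, n_genes=300, n_cells_per_type=80, n_shared_epithelial_markers=15,
        cell_types=[
            ps.CellTypeSpec(t, n_markers=10, epithelial=True)
            for t in ("luminal", "basal", "club", "hillock", "neuroendocrine")
        ]
        + [ps.CellTypeSpec(t, n_markers=10, epithelial=False) for t in ("fibroblast", "immune")],
    )
    return ps.simulate_reference(cfg)
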