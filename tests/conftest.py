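import warnings

import numpy as np
import pandas as pd
import pytest

from crossmod import CohortConfig, CountMatrix, generate_cohort

warnings.filterwarnings("ignore", message=".*Identity link.*")


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort at reduced size: 3 batches, 5 cell types,
    planted identity programs and activity module with a declining rejection
    trend."""
    cfg = CohortConfig(
        n_genes=500, n_cells_per_type_per_donor=15, n_module_genes=30,
        n_identity_genes=25, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose genes are generated independently (no planted programs,
    no module effect)."""
    cfg = CohortConfig(
        n_genes=400, n_cells_per_type_per_donor=20, n_celltypes=2,
        identity_strength=0.0, module_strength=0.0, batch_sigma=0.0,
        libsize_sigma=0.0, trend_effect=(1.0, 1.0, 1.0), seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def toy_counts():
    """A tiny deterministic 6-gene x 8-cell matrix with metadata."""
    rng = np.random.default_rng(0)
    values = rng.poisson(5.0, (6, 8)).astype(float)
    genes = [f"g{i}" for i in range(6)]
    cells = [f"c{i}" for i in range(8)]
    meta = pd.DataFrame({
        "batch": ["B0"] * 4 + ["B1"] * 4,
        "donor": ["d0"] * 8,
        "timepoint": ["T0", "T1"] * 4,
        "condition": ["stable"] * 4 + ["rejection"] * 4,
        "cell_type": ["CT0", "CT0", "CT1", "CT1"] * 2,
    }, index=pd.Index(cells, name="cell_id"))
    return CountMatrix(values, genes, cells, meta)
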