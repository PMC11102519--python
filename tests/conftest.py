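import numpy as np
import pandas as pd
import pytest

from eccdecon import AtlasSimConfig, build_reference, generate_synthetic_atlas
from eccdecon.containers import AnnotatedCellMatrix


@pytest.fixture(scope="session")
def small_atlas():
    """A compact well-separated synthetic atlas: 4 types, 2 donors, 80 genes."""
    cfg = AtlasSimConfig(n_types=4, n_subjects=2, n_genes=80,
                         markers_per_type=8, marker_log2_foldchange=3.0,
                         cells_per_type_per_subject=30, seed=11)
    cells, params = generate_synthetic_atlas(cfg)
    return cells, params


@pytest.fixture(scope="session")
def small_reference(small_atlas):
    cells, _ = small_atlas
    return build_reference(cells, min_cells_per_type=5)


@pytest.fixture()
def toy_cells():
    """5 cells, 3 genes, hand-set counts over two types and two donors."""
    counts = np.array(
        [
            [10.0, 0.0, 5.0, 2.0, 1.0],
            [0.0, 8.0, 5.0, 6.0, 3.0],
            [2.0, 2.0, 0.0, 2.0, 6.0],
        ]
    )
    return AnnotatedCellMatrix(
        counts=counts,
        gene_ids=["g1", "g2", "g3"],
        cell_type=np.array(["A", "B", "A", "B", "B"], dtype=object),
        subject=np.array(["s1", "s1", "s2", "s2", "s2"], dtype=object),
    )


@pytest.fixture()
def dirichlet_ecc():
    """100 samples x 5 types drawn from a Dirichlet, rows summing to one."""
    rng = np.random.default_rng(7)
    props = rng.dirichlet(np.ones(5), size=100)
    return pd.DataFrame(
        props,
        index=[f"sample{i}" for i in range(100)],
        columns=[f"type{k}" for k in range(5)],
    )
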