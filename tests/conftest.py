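import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mpkit.matrix import ExpressionMatrix
from mpkit.simulate import SimulationConfig, generate


def make_matrix(values, gene_ids=None, cell_ids=None, annotations=None,
                layer_state="raw") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    return ExpressionMatrix(
        values=sp.csr_matrix(values),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        annotations=annotations if annotations is not None else pd.DataFrame(),
        layer_state=layer_state,
    )


@pytest.fixture(scope="session")
def small_simulation():
    """One small two-entity simulation shared by read-only tests."""
    cfg = SimulationConfig(
        entities=["tumor_malignant", "inflamed_gut"],
        n_studies_per_entity=2,
        n_genes=300,
        n_cells_per_study=150,
        n_programs_per_entity=3,
        program_size=30,
        cross_entity_overlap={("tumor_malignant", "inflamed_gut"): 0.5},
        seed=7,
    )
    matrices, truth = generate(cfg)
    return cfg, matrices, truth
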