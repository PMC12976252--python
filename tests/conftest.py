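import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scprogression import SimConfig, generate_cohort
from scprogression.data_io import CountMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-patient paired cohort with planted effects, shared across tests."""
    cfg = SimConfig(
        n_patients=3,
        cells_per_sample=400,
        n_genes=800,
        n_clusters_per_patient=4,
        n_recurrent_degs=15,
        n_private_degs=15,
        n_markers_per_cluster=10,
        deg_log2fc=1.5,
        seed=11,
    )
    return cfg, generate_cohort(cfg)


def raw_matrix(counts, gene_prefix="G", cell_prefix="c") -> CountMatrix:
    """Wrap a dense integer array as a raw CountMatrix with generated ids."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    return CountMatrix(
        sp.csr_matrix(counts),
        np.array([f"{gene_prefix}{j}" for j in range(n_genes)], dtype=object),
        np.array([f"{cell_prefix}{i}" for i in range(n_cells)], dtype=object),
        layer="raw",
    )


@pytest.fixture
def toy_matrix():
    return raw_matrix


@pytest.fixture
def basic_annotation():
    def make(gene_ids, mito=(), non_coding=(), metabolic=()):
        return pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "is_protein_coding": [g not in non_coding for g in gene_ids],
                "is_metabolic": [g in metabolic for g in gene_ids],
                "is_mitochondrial": [g in mito for g in gene_ids],
            }
        )

    return make
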