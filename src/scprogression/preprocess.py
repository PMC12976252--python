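"""QC filtering, normalization, PCA embedding, and SNN clustering.

Defaults follow the upstream single-cell convention for 3' UMI data:
cells are kept with 250-4500 detected features and < 20% mitochondrial
counts; counts are library-size scaled to 10,000 and log1p transformed;
the embedding is an exact PCA of the scaled (clipped at +/-10) top-2000
highly variable genes; clustering builds a shared-nearest-neighbor graph
(Jaccard weights, pruned below 1/15) and optimizes modularity at a given
resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_io import NORMALIZED, RAW, CountMatrix

__all__ = ["QCReport", "Embedding", "qc_filter", "normalize_log1p", "pca_embed", "snn_cluster"]

LOW_FEATURES = "low_features"
HIGH_FEATURES = "high_features"
HIGH_MITO = "high_mito"


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_kept: int
    table: pd.DataFrame  # cell_id, n_features, pct_mito, kept, reasons


@dataclass
class Embedding:
    coordinates: np.ndarray
    n_components: int
    explained_variance_ratio: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape[1] != self.n_components:
            raise ValueError("embedding width does not match n_components")


def qc_filter(
    m: CountMatrix,
    ann: pd.DataFrame,
    min_features: int = 250,
    max_features: int = 4500,
    max_mito: float = 0.20,
):
    """Remove poor-quality cells from a raw count matrix.

    Keeps cells with ``min_features <= n_features <= max_features`` and
    ``pct_mito < max_mito`` (strict). ``n_features`` counts genes with at
    least one UMI; ``pct_mito`` is the mitochondrial share of total counts
    (defined as 0 for zero-count cells). Returns the filtered matrix and a
    :class:`QCReport` with a per-cell reason breakdown.
    """
    if m.layer != RAW:
        raise ValueError("qc_filter requires the raw layer")
    mito_genes = set(ann.loc[ann["is_mitochondrial"].astype(bool), "gene_id"])
    mito_idx = m.gene_index(mito_genes)

    X = m.values.tocsr()
    n_features = np.diff(X.indptr)  # nnz per cell row
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_counts = (
        np.asarray(X[:, mito_idx].sum(axis=1)).ravel()
        if mito_idx.size
        else np.zeros(m.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    low = n_features < min_features
    high = n_features > max_features
    mito_bad = pct_mito >= max_mito
    kept = ~(low | high | mito_bad)

    reasons = [
        [r for r, bad in ((LOW_FEATURES, low[i]), (HIGH_FEATURES, high[i]), (HIGH_MITO, mito_bad[i])) if bad]
        for i in range(m.n_cells)
    ]
    report = QCReport(
        n_cells_in=m.n_cells,
        n_cells_kept=int(kept.sum()),
        table=pd.DataFrame(
            {
                "cell_id": m.cell_ids,
                "n_features": n_features,
                "pct_mito": pct_mito,
                "kept": kept,
                "reasons": reasons,
            }
        ),
    )
    if report.n_cells_kept == 0:
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return m.subset_cells(kept), report


def normalize_log1p(m: CountMatrix, scale: float = 1e4) -> CountMatrix:
    """Library-size normalize to ``scale`` counts per cell and log1p (natural log).

    Sparsity is preserved: zero counts stay exactly zero. Zero-total cells
    are rejected by barcode; run :func:`qc_filter` first.
    """
    if m.layer != RAW:
        raise ValueError("normalize_log1p requires the raw layer")
    totals = np.asarray(m.values.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        bad = m.cell_ids[zero][0]
        raise ValueError(f"cell {bad!r} has zero total counts; run qc_filter first")
    X = m.values.astype(float).tocsr(copy=True)
    row_scale = scale / totals
    X.data *= np.repeat(row_scale, np.diff(X.indptr))
    X.data = np.log1p(X.data)
    return CountMatrix(X, m.gene_ids, m.cell_ids, layer=NORMALIZED)


def _select_hvg(X: sp.csr_matrix, n_hvg: int) -> np.ndarray:
    """Indices of the n_hvg genes with largest variance of normalized values."""
    n = X.shape[0]
    mean = np.asarray(X.mean(axis=0)).ravel()
    mean_sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (mean_sq - mean**2) * n / max(n - 1, 1)
    if n_hvg >= X.shape[1]:
        return np.arange(X.shape[1])
    order = np.argsort(-var, kind="stable")
    return np.sort(order[:n_hvg])


def pca_embed(
    m: CountMatrix,
    n_components: int = 15,
    n_hvg: int = 2000,
    clip: float = 10.0,
    solver: str = "auto",
    seed: int = 0,
) -> Embedding:
    """Embed cells by PCA of the scaled highly-variable-gene submatrix.

    Genes are restricted to the ``n_hvg`` most variable, standardized to
    zero mean / unit variance with values clipped at ``+/-clip``, then
    decomposed by exact full SVD (``solver='full'``). ``solver='auto'``
    switches to seeded randomized SVD above 1000 retained genes, which is
    deterministic for a fixed seed. Component signs are fixed by making
    each loading vector's largest-magnitude entry positive.
    """
    if m.layer != NORMALIZED:
        raise ValueError("pca_embed requires the normalized layer")
    if n_components >= min(m.n_cells, m.n_genes):
        raise ValueError("n_components must be smaller than min(cells, genes)")
    if n_hvg > m.n_genes:
        warnings.warn(
            f"n_hvg={n_hvg} exceeds the {m.n_genes} available genes; using all",
            stacklevel=2,
        )
    hvg = _select_hvg(m.values.tocsr(), n_hvg)
    X = np.asarray(m.values[:, hvg].todense(), dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = np.clip((X - mu) / sd, -clip, clip)

    from sklearn.decomposition import PCA

    if solver == "auto":
        solver = "full" if X.shape[1] <= 1000 else "randomized"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=seed)
    coords = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(n_components),
                        np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    coords = coords * flip[None, :]
    return Embedding(coords, n_components, pca.explained_variance_ratio_.copy())


def snn_cluster(
    e: Embedding,
    k_neighbors: int = 20,
    resolution: float = 1.5,
    prune: float = 1.0 / 15.0,
    seed: int = 0,
) -> np.ndarray:
    """Cluster cells on a shared-nearest-neighbor graph by modularity.

    Builds the Euclidean k-NN graph in the embedding (neighbor sets include
    the cell itself), weights cell pairs by the Jaccard overlap of their
    neighbor sets, prunes weights below ``prune``, and runs seeded Leiden
    modularity optimization at the given ``resolution``. Labels are 0-based
    and relabeled by decreasing cluster size.
    """
    import igraph as ig
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    n = e.coordinates.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(e.coordinates)
    _, idx = nn.kneighbors(e.coordinates)
    rows = np.repeat(np.arange(n), k_neighbors)
    A = sp.csr_matrix(
        (np.ones(n * k_neighbors), (rows, idx.ravel())), shape=(n, n)
    )
    inter = (A @ A.T).tocoo()  # |N(i) & N(j)| for pairs sharing neighbors
    jac = inter.data / (2 * k_neighbors - inter.data)
    keep = (jac >= prune) & (inter.row < inter.col)
    edges = np.column_stack([inter.row[keep], inter.col[keep]])
    weights = jac[keep]

    g = ig.Graph(n=n, edges=edges.tolist())
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=list(weights),
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    # relabel by decreasing size, ties broken by original label
    sizes = np.bincount(labels)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(order.size)
    return remap[labels]
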