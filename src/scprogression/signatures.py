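"""Gene-set scoring, metabolic transcript fractions, and related utilities.

The per-cell module score compares a gene set's mean normalized expression
with that of randomly sampled control genes drawn from the same
average-expression bins, so the score is centered at zero for sets with no
coherent signal. The per-cluster activity score summarizes a set's
pseudobulk expression as an average percentile rank across clusters,
shifted to [-0.5, 0.5]. The metabolic fraction is the share of a cell's
(or sample's) protein-coding transcripts that belong to metabolism
-associated genes. Sample-level condition comparisons use a permutation
test that sign-flips within patient for paired samples and permutes
labels among unpaired samples, accommodating mixed designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import RAW, CountMatrix, GeneSet

__all__ = [
    "ModuleScoreResult",
    "module_score",
    "activity_scores",
    "metabolic_fraction",
    "sample_mean_permutation_test",
    "orient_pseudotime",
]


@dataclass
class ModuleScoreResult:
    scores: pd.Series  # per cell
    gene_set: str
    n_bins: int
    n_ctrl: int
    seed: int


def module_score(
    m: CountMatrix,
    gs: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Per-cell gene-set score against expression-matched random controls.

    Genes are binned into ``n_bins`` equal-frequency bins of their mean
    normalized expression over all cells (ties broken by tiny seeded rank
    jitter). For each gene-set gene, ``n_ctrl`` control genes are sampled
    without replacement from its bin; controls are pooled across set genes
    with duplicates retained. The score is the set's mean expression minus
    the pooled controls' mean, per cell. Scores should be computed on the
    entire dataset under comparison, not per-subset.
    """
    if n_bins > m.n_genes:
        raise ValueError(f"n_bins={n_bins} exceeds the {m.n_genes} genes available")
    set_idx = m.gene_index(gs.genes)
    if set_idx.size == 0:
        raise ValueError(f"no genes of set {gs.name!r} present in the matrix")
    if set_idx.size < len(gs):
        warnings.warn(
            f"{len(gs) - set_idx.size} genes of set {gs.name!r} absent from the matrix",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    X = m.values.tocsc()
    gene_means = np.asarray(X.mean(axis=0)).ravel()

    # equal-frequency bins on jittered ranks (deterministic per seed)
    ranks = rankdata(gene_means, method="ordinal").astype(float)
    ranks += rng.uniform(-1e-9, 1e-9, size=ranks.size)
    order = np.argsort(ranks)
    bin_of = np.empty(m.n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b

    bins = [np.flatnonzero(bin_of == b) for b in range(n_bins)]
    ctrl_pool = []
    for g in set_idx:
        pool = bins[bin_of[g]]
        size = min(n_ctrl, pool.size)
        ctrl_pool.append(rng.choice(pool, size=size, replace=False))
    ctrl_idx = np.concatenate(ctrl_pool)

    # compute both means on per-cell shifted values (shift = the first set
    # gene's value): algebraically identical, but the shift makes the
    # set-vs-control cancellation exact when a cell is constant across genes
    shift = np.asarray(X[:, set_idx[0]].todense()).ravel()
    out = np.empty(m.n_cells)
    chunk = max(1, int(2e7 // max(ctrl_idx.size, 1)))
    for lo in range(0, m.n_cells, chunk):
        hi = min(lo + chunk, m.n_cells)
        s = shift[lo:hi, None]
        xs = np.asarray(X[lo:hi, set_idx].todense()) - s
        # pooled mean keeps duplicate draws (each control draw weighs equally)
        xc = np.asarray(X[lo:hi, ctrl_idx].todense()) - s
        out[lo:hi] = xs.mean(axis=1) - xc.sum(axis=1) / ctrl_idx.size
    scores = pd.Series(out, index=m.cell_ids, name=gs.name)
    return ModuleScoreResult(scores, gs.name, n_bins, n_ctrl, seed)


def activity_scores(m: CountMatrix, clusters, gene_sets) -> pd.DataFrame:
    """Percentile-rank activity of gene sets per cluster, in [-0.5, 0.5].

    Cluster pseudobulks are per-gene means of raw counts, library-size
    normalized (scale 1e4) and log1p transformed. For each gene, clusters
    receive mid-rank percentiles (rank - 0.5)/K; a set's score per cluster
    is the mean percentile over member genes minus 0.5, so ties land at 0
    and the stated bounds hold exactly.
    """
    if m.layer != RAW:
        raise ValueError("activity_scores requires the raw layer")
    cl = np.asarray(clusters)
    if cl.size != m.n_cells:
        raise ValueError("cluster labels must cover every cell")
    uniq = pd.unique(cl)
    K = len(uniq)
    if K < 2:
        raise ValueError("activity scores need at least 2 clusters")

    pb = np.zeros((K, m.n_genes))
    for i, c in enumerate(uniq):
        sel = cl == c
        pb[i] = np.asarray(m.values[sel].mean(axis=0)).ravel()
    totals = pb.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    pb = np.log1p(pb / totals * 1e4)

    # mid-rank percentile of each cluster, per gene
    pct = (rankdata(pb, axis=0, method="average") - 0.5) / K

    out = {}
    for gs in gene_sets:
        idx = m.gene_index(gs.genes)
        if idx.size == 0:
            warnings.warn(f"gene set {gs.name!r} has no genes in the matrix",
                          stacklevel=2)
            continue
        out[gs.name] = pct[:, idx].mean(axis=1) - 0.5
    return pd.DataFrame(out, index=pd.Index(uniq, name="cluster"))


def metabolic_fraction(
    m: CountMatrix,
    ann: pd.DataFrame,
    per: str = "cell",
    samples=None,
) -> pd.Series:
    """Share of protein-coding transcripts from metabolism-associated genes.

    ``per='cell'`` returns one fraction per cell; ``per='sample'`` pools
    counts within each sample (ratio of summed counts, i.e. the
    count-weighted mean of per-cell fractions) and requires ``samples``,
    a per-cell sample label. Units with zero protein-coding counts get NaN.
    """
    if m.layer != RAW:
        raise ValueError("metabolic_fraction requires the raw layer")
    ann = ann.set_index("gene_id") if "gene_id" in ann.columns else ann
    coding = set(ann.index[ann["is_protein_coding"].astype(bool)])
    metabolic = set(ann.index[ann["is_metabolic"].astype(bool)])
    stray = metabolic - coding
    if stray:
        warnings.warn(
            f"{len(stray)} metabolic genes are not protein-coding; intersecting",
            stacklevel=2,
        )
        metabolic &= coding
    cod_idx = m.gene_index(coding)
    met_idx = m.gene_index(metabolic)

    cod = np.asarray(m.values[:, cod_idx].sum(axis=1)).ravel()
    met = (
        np.asarray(m.values[:, met_idx].sum(axis=1)).ravel()
        if met_idx.size
        else np.zeros(m.n_cells)
    )
    if per == "cell":
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(cod > 0, met / np.maximum(cod, 1), np.nan)
        return pd.Series(frac, index=m.cell_ids, name="metabolic_fraction")
    if per == "sample":
        if samples is None:
            raise ValueError("per='sample' requires per-cell sample labels")
        df = pd.DataFrame({"sample": np.asarray(samples), "met": met, "cod": cod})
        agg = df.groupby("sample", sort=True).sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(agg["cod"] > 0, agg["met"] / agg["cod"], np.nan)
        return pd.Series(frac, index=agg.index, name="metabolic_fraction")
    raise ValueError(f"per must be 'cell' or 'sample', got {per!r}")


def sample_mean_permutation_test(
    values: pd.Series,
    design: pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p for a condition difference of sample means.

    ``values`` is one summary value per sample; ``design`` carries
    ``patient`` and ``timepoint`` (two conditions) per sample. Patients
    with both conditions contribute paired samples whose labels are
    swapped with probability 1/2 under the null; labels of unpaired
    samples are permuted globally among the unpaired, preserving the
    condition counts. Add-one two-sided p-value.
    """
    design = design.loc[values.index]
    tp = design["timepoint"].astype(str)
    conds = sorted(tp.unique())
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    c0, c1 = conds
    pat_counts = design.groupby("patient")["timepoint"].nunique()
    paired_patients = pat_counts.index[pat_counts == 2]
    is_paired = design["patient"].isin(paired_patients).to_numpy()

    vals = values.to_numpy(dtype=float)
    lab = (tp == c1).to_numpy()  # True = condition c1

    n_unpaired0 = int((~is_paired & ~lab).sum())
    n_unpaired1 = int((~is_paired & lab).sum())
    if len(paired_patients) == 0 and min(n_unpaired0, n_unpaired1) < 2:
        raise ValueError(
            "no paired patients and fewer than 2 unpaired samples per condition"
        )

    def stat(labels: np.ndarray) -> float:
        return vals[labels].mean() - vals[~labels].mean()

    obs = stat(lab)
    pair_rows = [
        np.flatnonzero((design["patient"] == p).to_numpy()) for p in paired_patients
    ]
    unpaired_rows = np.flatnonzero(~is_paired)
    unpaired_labels = lab[unpaired_rows]

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        perm = lab.copy()
        if pair_rows:
            flips = rng.random(len(pair_rows)) < 0.5
            for rows, flip in zip(pair_rows, flips):
                if flip:
                    perm[rows] = ~perm[rows]
        if unpaired_rows.size:
            perm[unpaired_rows] = rng.permutation(unpaired_labels)
        if abs(stat(perm)) >= abs(obs):
            exceed += 1
    return (1.0 + exceed) / (B + 1.0)


def orient_pseudotime(pt, timepoints) -> np.ndarray:
    """Rescale pseudotime to [0, 1] and orient it indolent -> active.

    After min-max rescaling, the trajectory is flipped (pt -> 1 - pt) when
    the mean pseudotime of indolent cells exceeds that of active cells, so
    0 reads as the indolent expression state and 1 as the active state.
    Constant input yields all 0.5 with a warning. The operation is an
    involution: orienting an oriented vector returns it unchanged.
    """
    pt = np.asarray(pt, dtype=float)
    tp = np.asarray(timepoints)
    for lbl in ("indolent", "active"):
        if not np.any(tp == lbl):
            raise ValueError(f"no {lbl!r} cells present")
    lo, hi = pt.min(), pt.max()
    if hi == lo:
        warnings.warn("constant pseudotime; returning 0.5 everywhere", stacklevel=2)
        return np.full_like(pt, 0.5)
    pt = (pt - lo) / (hi - lo)
    if pt[tp == "indolent"].mean() > pt[tp == "active"].mean():
        pt = 1.0 - pt
    return pt
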