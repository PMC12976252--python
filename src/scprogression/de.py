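"""Differential expression between paired conditions, and DEG recurrence.

Three routes mirror the analysis design:

* cell-level Wilcoxon rank-sum DE on normalized expression (the per-pair
  indolent-vs-active comparison), with the exact null for small groups and
  the tie/continuity-corrected normal approximation otherwise;
* pseudobulk negative-binomial likelihood-ratio DE on summed raw counts
  (the expanding-vs-shrinking cluster and cross-sample comparisons), with
  method-of-moments dispersions shrunk toward a trimmed common value;
* a gene-label permutation test for whether the number of genes called DEG
  in at least k patient pairs exceeds chance, resampling each pair's DEG
  count from that pair's own tested-gene universe.

DEG calls use adjusted p < 0.05 (strict) and |log2FC| >= 0.5 (non-strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln
from scipy.stats import chi2, norm, trim_mean

from ._utils import bh_adjust
from .data_io import NORMALIZED, RAW, CountMatrix

__all__ = [
    "DEG_ALPHA",
    "DEG_LFC",
    "PseudobulkMatrix",
    "RecurrenceResult",
    "expression_fraction_filter",
    "wilcoxon_de",
    "pseudobulk_aggregate",
    "nb_lrt_de",
    "recurrence_permutation_test",
]

DEG_ALPHA = 0.05
DEG_LFC = 0.5


def _flag_degs(table: pd.DataFrame, alpha: float, lfc: float) -> pd.DataFrame:
    table["is_deg"] = (table["p_adj"] < alpha) & (np.abs(table["log2fc"]) >= lfc)
    return table


def expression_fraction_filter(
    m: CountMatrix, cells=None, min_frac: float = 0.01
) -> np.ndarray:
    """Genes detected (count > 0) in at least ceil(min_frac * n) of the cells.

    Returns a boolean mask over ``m.gene_ids``.
    """
    X = m.values
    if cells is not None:
        idx = np.asarray(cells)
        if idx.dtype == bool:
            if not idx.any():
                raise ValueError("empty cell subset")
            X = X[idx]
        else:
            if idx.size == 0:
                raise ValueError("empty cell subset")
            X = X[idx]
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty cell subset")
    detected = np.asarray((X > 0).sum(axis=0)).ravel()
    return detected >= int(np.ceil(min_frac * n))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum DE
# ---------------------------------------------------------------------------

def _exact_mwu_pmf(n: int, m: int) -> np.ndarray:
    """Exact null pmf of the Mann-Whitney U statistic (no ties), u = 0..n*m."""
    # classic two-sample recurrence f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u)
    f = np.zeros((n + 1, n * m + 1))
    f[:, 0] = 1.0  # N(u; i, j=0) is a point mass at u = 0
    for j in range(1, m + 1):
        g = np.zeros_like(f)
        g[0, 0] = 1.0
        for i in range(1, n + 1):
            g[i] = f[i].copy()
            g[i, j:] += g[i - 1, : n * m + 1 - j]
        f = g
    counts = f[n]
    return counts / counts.sum()


def _exact_mwu_p(u: float, n: int, m: int, pmf: np.ndarray) -> float:
    """Two-sided exact p: doubled smaller tail, capped at 1."""
    u = int(round(u))
    lower = pmf[: u + 1].sum()
    upper = pmf[u:].sum()
    return min(1.0, 2.0 * min(lower, upper))


def _rank_rows(XT: np.ndarray):
    """Average (mid) ranks and tie terms per row of a genes x cells matrix.

    Returns ``(ranks, tie)`` where ``ranks[g, i]`` is the 1-based mid-rank
    of cell i within gene g and ``tie[g]`` is sum(t^3 - t) over tied
    groups. Fully vectorized: tie runs are delimited with cumulative
    max/min scans over run-start/run-end indices.
    """
    g, n = XT.shape
    order = np.argsort(XT, axis=1, kind="stable")
    sv = np.take_along_axis(XT, order, axis=1)
    new_run = np.ones((g, n), dtype=bool)
    new_run[:, 1:] = sv[:, 1:] != sv[:, :-1]
    cols = np.arange(n)
    # index of each position's run start (cummax) and run end (reverse cummin)
    start = np.maximum.accumulate(np.where(new_run, cols, 0), axis=1)
    run_end_marker = np.ones((g, n), dtype=bool)
    run_end_marker[:, :-1] = new_run[:, 1:]
    end = np.minimum.accumulate(
        np.where(run_end_marker, cols, n - 1)[:, ::-1], axis=1
    )[:, ::-1]
    avg = (start + end + 2) / 2.0  # ranks start+1 .. end+1, averaged
    ranks = np.empty((g, n))
    np.put_along_axis(ranks, order, avg, axis=1)
    t = np.where(new_run, end - start + 1, 0).astype(float)
    tie = (t**3 - t).sum(axis=1)
    return ranks, tie


def wilcoxon_de(
    m: CountMatrix,
    group_a,
    group_b,
    method: str = "auto",
    alpha: float = DEG_ALPHA,
    lfc_threshold: float = DEG_LFC,
    exact_max: int = 8,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE between two cell groups.

    Operates on the normalized (log1p) layer. ``method='auto'`` uses the
    exact U distribution when both groups have at most ``exact_max`` cells
    and the gene has no ties, else the normal approximation with tie and
    continuity correction. The fold change is computed on de-logged means:
    ``log2((mean(expm1 x_A) + 1) / (mean(expm1 x_B) + 1))``.

    Returns a DataFrame indexed by gene with log2fc, p, p_adj (BH), the
    expressing-cell fractions pct_a/pct_b, and the DEG flag.
    """
    if m.layer != NORMALIZED:
        raise ValueError("wilcoxon_de requires the normalized layer")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    ia = _as_index(group_a, m.n_cells)
    ib = _as_index(group_b, m.n_cells)
    na, nb = ia.size, ib.size
    if na == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    if min(na, nb) < 3:
        warnings.warn("a group has fewer than 3 cells; p-values are unstable",
                      stacklevel=2)

    Xa = np.asarray(m.values[ia].todense(), dtype=float)
    Xb = np.asarray(m.values[ib].todense(), dtype=float)
    n = na + nb
    # rank per gene on a contiguous genes x cells layout (much faster than
    # column-wise ranking of the cells x genes matrix)
    XT = np.ascontiguousarray(np.hstack([Xa.T, Xb.T]))

    ranks, tie = _rank_rows(XT)
    ra = ranks[:, :na].sum(axis=1)
    U = ra - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    sigma2 = na * nb / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))

    with np.errstate(invalid="ignore", divide="ignore"):
        z = (U - mu - 0.5 * np.sign(U - mu)) / sigma
    p = np.where(sigma > 0, 2.0 * norm.sf(np.abs(z)), 1.0)
    p = np.minimum(p, 1.0)

    want_exact = method == "exact" or (
        method == "auto" and max(na, nb) <= exact_max
    )
    if want_exact:
        pmf = _exact_mwu_pmf(na, nb)
        no_ties = tie == 0
        if method == "exact" and not no_ties.all():
            warnings.warn(
                "ties present; falling back to the normal approximation for tied genes",
                stacklevel=2,
            )
        for j in np.flatnonzero(no_ties):
            p[j] = _exact_mwu_p(U[j], na, nb, pmf)

    mean_a = np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    pct_a = (Xa > 0).mean(axis=0)
    pct_b = (Xb > 0).mean(axis=0)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "p_adj": bh_adjust(p),
            "pct_a": pct_a,
            "pct_b": pct_b,
        },
        index=pd.Index(m.gene_ids, name="gene"),
    )
    return _flag_degs(table, alpha, lfc_threshold)


def _as_index(sel, n: int) -> np.ndarray:
    sel = np.asarray(sel)
    if sel.dtype == bool:
        if sel.size != n:
            raise ValueError("boolean selector length mismatch")
        return np.flatnonzero(sel)
    return sel.astype(int)


# ---------------------------------------------------------------------------
# Pseudobulk NB LRT
# ---------------------------------------------------------------------------

@dataclass
class PseudobulkMatrix:
    """Per-group sums of raw counts with group metadata."""

    counts: pd.DataFrame  # groups x genes, integer
    meta: pd.DataFrame  # index = group, column n_cells (+ caller columns)


def pseudobulk_aggregate(m: CountMatrix, grouping) -> PseudobulkMatrix:
    """Sum raw counts per group of cells (one group per cell).

    Groups with zero cells (empty categories) are dropped with a warning.
    """
    if m.layer != RAW:
        raise ValueError("pseudobulk_aggregate requires the raw layer")
    g = pd.Series(np.asarray(grouping, dtype=object))
    if g.size != m.n_cells:
        raise ValueError("grouping length must equal the number of cells")
    if g.isna().any():
        raise ValueError("every cell must be assigned to a group")
    cats = pd.unique(g)
    cat_index = {c: i for i, c in enumerate(cats)}
    rows = g.map(cat_index).to_numpy()
    ind = sp.csr_matrix(
        (np.ones(m.n_cells), (rows, np.arange(m.n_cells))),
        shape=(len(cats), m.n_cells),
    )
    counts = np.asarray((ind @ m.values).todense()).astype(np.int64)
    n_cells = np.bincount(rows, minlength=len(cats))
    keep = n_cells > 0
    if not keep.all():
        warnings.warn("dropping empty pseudobulk groups", stacklevel=2)
    return PseudobulkMatrix(
        counts=pd.DataFrame(counts[keep], index=pd.Index(cats[keep], name="group"),
                            columns=m.gene_ids),
        meta=pd.DataFrame({"n_cells": n_cells[keep]},
                          index=pd.Index(cats[keep], name="group")),
    )


def _nb_loglik(y, mu, alpha: float) -> float:
    if alpha < 1e-10:
        return float(np.sum(y * np.log(np.maximum(mu, 1e-300)) - mu - gammaln(y + 1)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _nb_irls(y, X, offset, alpha: float, max_iter: int = 50, tol: float = 1e-10):
    """Fit a log-link NB2 GLM with known dispersion by Fisher scoring."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(np.maximum(y.mean(), 0.5)) - offset.mean()
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / np.maximum(mu, 1e-12)
        XtW = X.T * W
        try:
            beta_new = np.linalg.solve(XtW @ X + 1e-10 * np.eye(p), XtW @ z)
        except np.linalg.LinAlgError:
            break
        ll = _nb_loglik(y, np.exp(np.clip(X @ beta_new + offset, -30, 30)), alpha)
        if not np.isfinite(ll):
            break
        beta = beta_new
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1):
            ll_old = ll
            break
        ll_old = ll
    mu = np.exp(np.clip(X @ beta + offset, -30, 30))
    return beta, _nb_loglik(y, mu, alpha)


def nb_lrt_de(
    pb: PseudobulkMatrix,
    condition,
    patient=None,
    alpha_deg: float = DEG_ALPHA,
    lfc_threshold: float = DEG_LFC,
    shrink_prior: float = 10.0,
) -> pd.DataFrame:
    """Pseudobulk NB GLM likelihood-ratio DE between two condition levels.

    Each gene is modeled as NB with log link and offset log(library size);
    per-gene method-of-moments dispersions are shrunk toward the 10%
    trimmed-mean common dispersion with weight n/(n + ``shrink_prior``),
    n = number of pseudobulk groups. The condition coefficient (second
    sorted level vs the first) is tested by LRT against the nested model
    (intercept, plus patient blocks when given); p from chi-square, df=1.
    """
    Y = pb.counts.to_numpy()
    if not np.allclose(Y, np.round(Y)):
        raise ValueError("pseudobulk counts must be integers (raw-count contract)")
    Y = np.round(Y).astype(np.int64)
    n_groups, n_genes = Y.shape
    cond = pd.Series(np.asarray(condition, dtype=object), index=pb.counts.index)
    levels = sorted(pd.unique(cond))
    if len(levels) != 2:
        raise ValueError(f"condition must have exactly 2 levels, got {levels}")
    x_cond = (cond == levels[1]).to_numpy().astype(float)
    per_level = cond.value_counts()
    if (per_level < 2).any():
        warnings.warn(
            "fewer than 2 pseudobulk groups in a condition level; "
            "dispersion estimates rely on the common value",
            stacklevel=2,
        )

    lib = Y.sum(axis=1).astype(float)
    if (lib == 0).any():
        raise ValueError("pseudobulk group with zero total counts")
    offset = np.log(lib)

    cols = [np.ones(n_groups)]
    if patient is not None:
        pat = pd.Series(np.asarray(patient, dtype=object), index=pb.counts.index)
        dummies = pd.get_dummies(pat, drop_first=True).to_numpy(dtype=float)
        cols.extend(dummies.T)
    X_red = np.column_stack(cols)
    X_full = np.column_stack(cols + [x_cond])

    # method-of-moments dispersion per gene from full-model fitted means
    # (reduces to offset-adjusted level means in the unpaired design), with
    # a residual-df correction for the p mean parameters consumed
    p_full = X_full.shape[1]
    resid_df = max(n_groups - p_full, 1)
    df_scale = n_groups / resid_df
    mu_hat = np.zeros_like(Y, dtype=float)
    if patient is None:
        for lev in levels:
            sel = (cond == lev).to_numpy()
            rate = Y[sel].sum(axis=0) / lib[sel].sum()
            mu_hat[sel] = np.outer(lib[sel], rate)
    else:
        disp0 = 0.1  # pilot dispersion for the mean fit only
        for j in range(n_genes):
            if Y[:, j].sum() == 0:
                continue
            beta, _ = _nb_irls(Y[:, j], X_full, offset, disp0)
            mu_hat[:, j] = np.exp(np.clip(X_full @ beta + offset, -30, 30))
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (df_scale * (Y - mu_hat) ** 2 - mu_hat).sum(axis=0)
        den = (mu_hat**2).sum(axis=0)
        disp_g = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    disp_g = np.clip(disp_g, 1e-8, 10.0)
    expressed = Y.sum(axis=0) > 0
    disp_common = float(trim_mean(disp_g[expressed], 0.1)) if expressed.any() else 0.1
    w = n_groups / (n_groups + shrink_prior)
    disp = np.clip(w * disp_g + (1 - w) * disp_common, 1e-8, 10.0)

    log2fc = np.zeros(n_genes)
    pvals = np.ones(n_genes)
    for j in range(n_genes):
        y = Y[:, j]
        if y.sum() == 0:
            continue
        a = disp[j]
        beta_f, ll_f = _nb_irls(y, X_full, offset, a)
        _, ll_r = _nb_irls(y, X_red, offset, a)
        lrt = max(0.0, 2.0 * (ll_f - ll_r))
        pvals[j] = chi2.sf(lrt, df=1)
        log2fc[j] = beta_f[-1] / np.log(2.0)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": bh_adjust(pvals),
            "pct_a": np.nan,
            "pct_b": np.nan,
            "dispersion": disp,
        },
        index=pb.counts.columns.rename("gene"),
    )
    return _flag_degs(table, alpha_deg, lfc_threshold)


# ---------------------------------------------------------------------------
# Cross-pair DEG recurrence
# ---------------------------------------------------------------------------

@dataclass
class RecurrenceResult:
    """Observed DEG multiplicity spectrum vs a gene-label permutation null."""

    histogram: pd.Series  # multiplicity -> number of genes (observed)
    observed_count_ge_k: int
    p: float
    k: int
    B: int
    seed: int
    null_counts: np.ndarray  # S_b for each permutation


def recurrence_permutation_test(
    deg_sets: Mapping[str, set],
    universes: Mapping[str, set],
    B: int = 10_000,
    seed: int = 0,
    k: int = 2,
) -> RecurrenceResult:
    """One-sided permutation test for cross-pair DEG recurrence.

    The statistic S is the number of genes called DEG in at least ``k``
    pairs. Each null draw resamples, for every pair independently,
    ``|DEG_i|`` genes uniformly without replacement from that pair's own
    tested-gene universe; p = (1 + #{S_b >= S_obs}) / (B + 1).
    """
    pairs = list(deg_sets)
    if set(pairs) - set(universes):
        raise ValueError("every DEG set needs a matching universe")
    for pid in pairs:
        uni = universes[pid]
        if not uni:
            raise ValueError(f"empty universe for pair {pid!r}")
        extra = set(deg_sets[pid]) - set(uni)
        if extra:
            raise ValueError(f"pair {pid!r}: DEGs outside the universe: {sorted(extra)[:3]}")

    all_genes = sorted(set().union(*[set(universes[p]) for p in pairs]))
    gidx = {g: i for i, g in enumerate(all_genes)}
    n_genes = len(all_genes)

    mult = np.zeros(n_genes, dtype=np.int32)
    for pid in pairs:
        for g in deg_sets[pid]:
            mult[gidx[g]] += 1
    s_obs = int((mult >= k).sum())
    hist = pd.Series(
        {j: int((mult == j).sum()) for j in range(1, len(pairs) + 1)},
        name="n_genes",
    )
    hist.index.name = "multiplicity"

    uni_idx = {
        pid: np.array([gidx[g] for g in universes[pid]], dtype=np.int64)
        for pid in pairs
    }
    sizes = {pid: len(deg_sets[pid]) for pid in pairs}

    rng = np.random.default_rng(seed)
    null_counts = np.zeros(B, dtype=np.int64)
    counts = np.zeros(n_genes, dtype=np.int16)
    for b in range(B):
        counts[:] = 0
        for pid in pairs:
            m_i = sizes[pid]
            if m_i == 0:
                continue
            draw = rng.choice(uni_idx[pid], size=m_i, replace=False)
            counts[draw] += 1
        null_counts[b] = int((counts >= k).sum())
    p = (1.0 + np.sum(null_counts >= s_obs)) / (B + 1.0)
    return RecurrenceResult(hist, s_obs, float(p), k, B, seed, null_counts)
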