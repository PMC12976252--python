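"""Synthetic paired two-time-point cohorts with planted ground truth.

Each simulated patient contributes an indolent and an active sample. Cells
are allocated to subclonal clusters by a multinomial whose proportions
differ between time points for planted expanding/shrinking clusters by an
exact configured log2 fold-difference. UMI counts follow a
negative-binomial (gamma-Poisson) law with log-normal library sizes and a
shared log-normal baseline expression profile. Planted effects are
multiplicative on the mean, so true log2 fold-changes equal the configured
values: patient-restricted DEGs (recurrent in >= 2 patients or private to
one) act on the active time point; cluster marker programs act on a
cluster at both time points (giving subclones the transcriptional
distinctness real subclones have, so graph clustering can recover them);
signature-set effects act on planted expanding clusters. Mitochondrial
genes are mean-boosted to hit a target mitochondrial fraction in
expectation. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_io import CountMatrix, GeneSet, make_cell_table

__all__ = [
    "SimConfig",
    "SimTruth",
    "SignatureSpec",
    "VariantSpec",
    "generate_cohort",
    "inject_variants",
    "derive_cluster_props",
    "simulate_composition_pair",
    "default_variant_specs",
]


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SignatureSpec:
    """A planted gene-set effect: multiplier on set genes per cluster class."""

    name: str
    n_genes: int = 50
    genes: Optional[tuple] = None
    multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"expanding": 2.0}
    )


@dataclass(frozen=True)
class VariantSpec:
    """A somatic variant shared by both time points of the WGS pairs."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf_indolent: float
    vaf_active: float
    depth: int = 500


def default_variant_specs() -> list:
    """Variant panel emulating longitudinal clonal outgrowth.

    Three mono-allelic ATM-like lesions rise from ~0.70 to ~0.91 mean VAF
    between time points while JAK/STAT-pathway subclones stay flat.
    """
    return [
        VariantSpec("ATM", "chr11", 108_236_000, "C", "T", 0.6977, 0.9133),
        VariantSpec("ATM", "chr11", 108_272_000, "G", "A", 0.6977, 0.9133),
        VariantSpec("ATM", "chr11", 108_330_000, "A", "G", 0.6977, 0.9133),
        VariantSpec("JAK3", "chr19", 17_835_000, "G", "T", 0.15, 0.15),
        VariantSpec("STAT5B", "chr17", 42_204_000, "C", "A", 0.12, 0.12),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a paired longitudinal leukemia cohort at desk scale:
    11 patients sampled twice, a few thousand cells and genes per sample,
    subclonal clusters of which one expands and one shrinks four-fold in
    proportion, and planted recurrent plus patient-private DEGs.
    """

    n_patients: int = 11
    cells_per_sample: int = 3000
    n_genes: int = 5000
    n_clusters_per_patient: int = 8
    # planted (patient_index, cluster) -> target log2 proportion difference
    planted_expanding: Optional[Mapping] = None
    planted_mass: float = 0.25
    cluster_props_indolent: Optional[Mapping] = None
    cluster_props_active: Optional[Mapping] = None
    n_recurrent_degs: int = 50
    n_private_degs: int = 100
    deg_log2fc: float = 1.5
    n_markers_per_cluster: int = 25
    marker_log2fc: float = 2.0
    signature_sets: Optional[Sequence[SignatureSpec]] = None
    pct_mito_mean: float = 0.05
    libsize_lognormal: tuple = (np.log(2500.0), 0.35)
    nb_dispersion: float = 0.3
    frac_metabolic: float = 0.10
    frac_coding: float = 0.80
    frac_mito: float = 0.005
    variant_specs: Optional[Sequence[VariantSpec]] = None
    keep_expected: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "cells_per_sample", "n_genes",
                     "n_clusters_per_patient"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        for name in ("pct_mito_mean", "frac_metabolic", "frac_coding", "frac_mito"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigError(f"{name} must be in [0, 1)")
        if self.planted_expanding is None:
            planted = {}
            for p in range(self.n_patients):
                if self.n_clusters_per_patient >= 2:
                    planted[(p, 0)] = 2.0
                    planted[(p, 1)] = -2.0
            object.__setattr__(self, "planted_expanding", planted)
        n_needed = self.n_recurrent_degs + self.n_private_degs
        n_markers = (self.n_patients * self.n_clusters_per_patient
                     * self.n_markers_per_cluster)
        if n_needed + n_markers > self.n_genes:
            raise ConfigError(
                f"{n_needed} planted DEGs + {n_markers} marker genes exceed "
                f"{self.n_genes} genes"
            )
        if self.n_recurrent_degs > 0 and self.n_patients < 2:
            raise ConfigError("recurrent DEGs need at least 2 patients")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated cohort."""

    expanding_clusters: set  # {(patient_id, cluster)}
    shrinking_clusters: set
    deg_table: pd.DataFrame  # patient_id, gene, true_log2fc
    recurrent_genes: set
    private_genes: set
    marker_genes: dict  # (patient_id, cluster) -> list of genes
    signature_effect_table: pd.DataFrame  # set, class, multiplier
    signature_gene_sets: list  # GeneSet objects
    cluster_props: pd.DataFrame  # patient_id, cluster, p_indolent, p_active
    expected_profiles: Optional[dict] = None  # (patient, tp) -> (K, G) mean matrix


def derive_cluster_props(
    n_clusters: int,
    planted: Mapping[int, float],
    planted_mass: float = 0.25,
) -> tuple:
    """Indolent/active proportion vectors realizing planted log2 differences.

    When planted effects include both signs, the mass gained by expanding
    clusters is exactly offset by shrinking ones and every non-planted
    cluster keeps a log2 fold-difference of exactly 0. With one-sided
    effects the remaining clusters absorb the mass change proportionally
    (their common residual log2 difference is reported by the caller's
    truth table).
    """
    for c, d in planted.items():
        if not (0 <= c < n_clusters):
            raise ConfigError(f"planted cluster {c} out of range")
        if d == 0:
            raise ConfigError("planted log2 differences must be non-zero")
    if not (0 < planted_mass < 1):
        raise ConfigError("planted_mass must be in (0, 1)")
    p_ind = np.zeros(n_clusters)
    p_act = np.zeros(n_clusters)
    pos = {c: d for c, d in planted.items() if d > 0}
    neg = {c: d for c, d in planted.items() if d < 0}
    if pos and neg:
        # x_c = t/(2^d - 1) for expanding, s/(1 - 2^d) for shrinking with
        # n_pos * t = n_neg * s keeps total mass constant across time points
        bracket = sum(1.0 / (2.0**d - 1.0) for d in pos.values()) + (
            len(pos) / len(neg)
        ) * sum(1.0 / (1.0 - 2.0**d) for d in neg.values())
        t = planted_mass / bracket
        s = len(pos) * t / len(neg)
        for c, d in pos.items():
            p_ind[c] = t / (2.0**d - 1.0)
        for c, d in neg.items():
            p_ind[c] = s / (1.0 - 2.0**d)
        for c, d in planted.items():
            p_act[c] = p_ind[c] * 2.0**d
    elif planted:
        share = planted_mass / len(planted)
        for c, d in planted.items():
            p_ind[c] = share
            p_act[c] = share * 2.0**d
    others = [c for c in range(n_clusters) if c not in planted]
    if others:
        rest_ind = 1.0 - p_ind.sum()
        rest_act = 1.0 - p_act.sum()
        if rest_ind <= 0 or rest_act <= 0:
            raise ConfigError("planted proportions exceed the whole")
        p_ind[others] = rest_ind / len(others)
        p_act[others] = rest_act / len(others)
    else:
        p_ind /= p_ind.sum()
        p_act /= p_act.sum()
    if abs(p_ind.sum() - 1) > 1e-9 or abs(p_act.sum() - 1) > 1e-9:
        raise ConfigError("cluster proportions do not sum to 1")
    return p_ind, p_act


def simulate_composition_pair(
    n_cells_per_sample: int,
    n_clusters: int,
    planted: Optional[Mapping[int, float]] = None,
    planted_mass: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Composition-only pair: per-cell (timepoint, cluster) labels.

    With ``planted=None`` the pair is exchangeable between time points
    (a null pair). Cluster proportions at the indolent time point are
    uniform outside the planted clusters.
    """
    rng = np.random.default_rng(seed)
    if planted:
        p_ind, p_act = derive_cluster_props(n_clusters, planted, planted_mass)
    else:
        p_ind = p_act = np.full(n_clusters, 1.0 / n_clusters)
    rows = []
    for tp, props in (("indolent", p_ind), ("active", p_act)):
        counts = rng.multinomial(n_cells_per_sample, props)
        for c, n in enumerate(counts):
            rows.extend([(tp, c)] * n)
    return pd.DataFrame(rows, columns=["timepoint", "cluster"])


def _gene_universe(cfg: SimConfig, rng: np.random.Generator):
    """Gene names, annotation flags, and the baseline expression profile."""
    n = cfg.n_genes
    n_mito = max(1, round(cfg.frac_mito * n)) if cfg.frac_mito > 0 else 0
    names = np.array(
        [f"MT-G{i:04d}" for i in range(n_mito)]
        + [f"G{i:05d}" for i in range(n - n_mito)],
        dtype=object,
    )
    is_mito = np.zeros(n, dtype=bool)
    is_mito[:n_mito] = True
    is_coding = np.zeros(n, dtype=bool)
    n_coding = round(cfg.frac_coding * n)
    coding_idx = np.concatenate(
        [np.arange(n_mito),
         rng.choice(np.arange(n_mito, n), size=max(0, n_coding - n_mito),
                    replace=False)]
    )
    is_coding[coding_idx] = True
    is_metab = np.zeros(n, dtype=bool)
    n_metab = round(cfg.frac_metabolic * n)
    metab_pool = np.setdiff1d(coding_idx, np.arange(n_mito))
    is_metab[rng.choice(metab_pool, size=min(n_metab, metab_pool.size),
                        replace=False)] = True

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    if n_mito:
        s_mito = base[is_mito].sum()
        s_rest = base[~is_mito].sum()
        target = cfg.pct_mito_mean
        if target > 0:
            base[is_mito] *= target * s_rest / ((1.0 - target) * s_mito)
    base /= base.sum()
    ann = pd.DataFrame(
        {
            "gene_id": names,
            "is_protein_coding": is_coding,
            "is_metabolic": is_metab,
            "is_mitochondrial": is_mito,
        }
    )
    return names, ann, base


def generate_cohort(cfg: SimConfig):
    """Simulate the paired cohort.

    Returns ``(counts, cells, annotation, truth)``: a raw
    :class:`CountMatrix` over all samples, the per-cell metadata table
    (with true cluster labels), the gene annotation table, and the
    :class:`SimTruth` record of every planted effect.
    """
    rng = np.random.default_rng(cfg.seed)
    names, ann, base = _gene_universe(cfg, rng)
    n_genes = cfg.n_genes
    K = cfg.n_clusters_per_patient
    patients = [f"p{i + 1}" for i in range(cfg.n_patients)]

    # --- planted DEGs -----------------------------------------------------
    mito_or_reserved = ann["is_mitochondrial"].to_numpy()
    free = np.flatnonzero(~mito_or_reserved)
    free = rng.permutation(free)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = free[cursor:cursor + k]
        cursor += k
        return out

    recurrent_idx = take(cfg.n_recurrent_degs)
    private_idx = take(cfg.n_private_degs)
    deg_rows = []
    deg_mult = {p: np.ones(n_genes) for p in patients}  # active-timepoint factor
    for g in recurrent_idx:
        n_pat = int(rng.integers(2, cfg.n_patients + 1))
        chosen = rng.choice(cfg.n_patients, size=n_pat, replace=False)
        sign = float(rng.choice([-1.0, 1.0]))
        for pi in chosen:
            deg_mult[patients[pi]][g] *= 2.0 ** (sign * cfg.deg_log2fc)
            deg_rows.append((patients[pi], names[g], sign * cfg.deg_log2fc))
    for j, g in enumerate(private_idx):
        pi = int(rng.integers(cfg.n_patients))
        sign = float(rng.choice([-1.0, 1.0]))
        deg_mult[patients[pi]][g] *= 2.0 ** (sign * cfg.deg_log2fc)
        deg_rows.append((patients[pi], names[g], sign * cfg.deg_log2fc))
    deg_table = pd.DataFrame(deg_rows,
                             columns=["patient_id", "gene", "true_log2fc"])

    # --- cluster marker programs (same at both time points) ---------------
    marker_genes = {}
    marker_mult = {}  # (patient, cluster) -> per-gene factor
    for p in patients:
        for c in range(K):
            idx = take(cfg.n_markers_per_cluster)
            marker_genes[(p, c)] = [names[g] for g in idx]
            v = np.ones(n_genes)
            v[idx] = 2.0**cfg.marker_log2fc
            marker_mult[(p, c)] = v

    # --- cluster proportions and classes ----------------------------------
    expanding, shrinking = set(), set()
    props_rows = []
    props = {}
    for pi, p in enumerate(patients):
        planted_p = {
            c: d for (ppi, c), d in cfg.planted_expanding.items() if ppi == pi
        }
        if cfg.cluster_props_indolent is not None:
            p_ind = np.asarray(cfg.cluster_props_indolent[pi], dtype=float)
            p_act = np.asarray(cfg.cluster_props_active[pi], dtype=float)
            for v in (p_ind, p_act):
                if abs(v.sum() - 1) > 1e-9:
                    raise ConfigError("cluster proportions must sum to 1")
        else:
            p_ind, p_act = derive_cluster_props(K, planted_p, cfg.planted_mass)
        props[p] = (p_ind, p_act)
        for c in range(K):
            props_rows.append((p, c, p_ind[c], p_act[c]))
        for c, d in planted_p.items():
            (expanding if d > 0 else shrinking).add((p, c))
    cluster_props = pd.DataFrame(
        props_rows, columns=["patient_id", "cluster", "p_indolent", "p_active"]
    )

    # --- signature effects (apply in planted expanding clusters) ----------
    sig_sets, sig_rows = [], []
    sig_mult = {}  # set name -> per-gene factor by class
    specs = list(cfg.signature_sets or [])
    for spec in specs:
        if spec.genes is not None:
            gene_names = list(spec.genes)
            idx = np.array([np.flatnonzero(names == g)[0] for g in gene_names])
        else:
            idx = take(spec.n_genes)
            gene_names = [names[g] for g in idx]
        sig_sets.append(GeneSet(spec.name, tuple(gene_names)))
        for cls, mult in spec.multipliers.items():
            if mult <= 0:
                raise ConfigError("signature multipliers must be positive")
            v = np.ones(n_genes)
            v[idx] = mult
            sig_mult[(spec.name, cls)] = v
            sig_rows.append((spec.name, cls, mult))
    signature_effect_table = pd.DataFrame(
        sig_rows, columns=["set", "class", "multiplier"]
    )

    def cluster_class(p: str, c: int) -> str:
        if (p, c) in expanding:
            return "expanding"
        if (p, c) in shrinking:
            return "shrinking"
        return "stable"

    # --- draw cells --------------------------------------------------------
    meanlog, sdlog = cfg.libsize_lognormal
    blocks, cell_rows = [], []
    expected = {} if cfg.keep_expected else None
    for p in patients:
        p_ind, p_act = props[p]
        for tp, pv in (("indolent", p_ind), ("active", p_act)):
            sample = f"{p}_{tp}"
            counts_per_cluster = rng.multinomial(cfg.cells_per_sample, pv)
            sample_profiles = np.zeros((K, n_genes))
            for c in range(K):
                profile = base * marker_mult[(p, c)]
                if tp == "active":
                    profile = profile * deg_mult[p]
                cls = cluster_class(p, c)
                for (sname, scls), v in sig_mult.items():
                    if scls == cls:
                        profile = profile * v
                sample_profiles[c] = profile
            if expected is not None:
                expected[(p, tp)] = sample_profiles.copy()
            for c in range(K):
                n_c = int(counts_per_cluster[c])
                if n_c == 0:
                    continue
                lib = rng.lognormal(meanlog, sdlog, size=n_c)
                mu = np.outer(lib, sample_profiles[c])
                lam = rng.gamma(shape=1.0 / cfg.nb_dispersion,
                                scale=mu * cfg.nb_dispersion)
                counts = rng.poisson(lam)
                blocks.append(sp.csr_matrix(counts))
                start = len(cell_rows)
                for i in range(n_c):
                    cell_rows.append(
                        (f"{sample}_c{c}_{start + i}", p, sample, tp, c)
                    )
    values = sp.vstack(blocks).tocsr()
    cells_df = pd.DataFrame(
        cell_rows, columns=["cell_id", "patient_id", "sample_id", "timepoint",
                            "cluster"],
    )
    m = CountMatrix(values.astype(np.int64), names,
                    cells_df["cell_id"].to_numpy(), layer="raw")

    mito_idx = np.flatnonzero(ann["is_mitochondrial"].to_numpy())
    totals = np.asarray(m.values.sum(axis=1)).ravel()
    mito = np.asarray(m.values[:, mito_idx].sum(axis=1)).ravel()
    cells = make_cell_table(
        cells_df["cell_id"], cells_df["patient_id"], cells_df["sample_id"],
        cells_df["timepoint"], cluster=cells_df["cluster"].to_numpy(),
        n_features=np.diff(m.values.indptr),
        pct_mito=np.where(totals > 0, mito / np.maximum(totals, 1), 0.0),
    )

    truth = SimTruth(
        expanding_clusters=expanding,
        shrinking_clusters=shrinking,
        deg_table=deg_table,
        recurrent_genes={names[g] for g in recurrent_idx},
        private_genes={names[g] for g in private_idx},
        marker_genes=marker_genes,
        signature_effect_table=signature_effect_table,
        signature_gene_sets=sig_sets,
        cluster_props=cluster_props,
        expected_profiles=expected,
    )
    return m, cells, ann, truth


def inject_variants(cfg: SimConfig, truth: Optional[SimTruth] = None):
    """Draw binomial alt-read counts for the configured variant panel.

    Returns ``(indolent, active)`` variant tables over identical loci.
    """
    specs = list(cfg.variant_specs or default_variant_specs())
    for s in specs:
        if s.depth <= 0:
            raise ConfigError(f"variant {s.gene}:{s.pos}: depth must be positive")
        for v in (s.vaf_indolent, s.vaf_active):
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"variant {s.gene}:{s.pos}: VAF outside [0, 1]")
    rng = np.random.default_rng(cfg.seed + 1)
    tables = []
    for which in ("vaf_indolent", "vaf_active"):
        rows = []
        for s in specs:
            alt = int(rng.binomial(s.depth, getattr(s, which)))
            rows.append(
                {
                    "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
                    "depth": s.depth, "alt_reads": alt, "vaf": alt / s.depth,
                    "pop_af": np.nan, "dbsnp_maf": np.nan, "topmed_maf": np.nan,
                    "gene": s.gene,
                }
            )
        tables.append(pd.DataFrame(rows))
    return tables[0], tables[1]
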