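"""End-to-end orchestration: simulate/load -> QC -> cluster -> dynamics ->
DE -> recurrence -> scores -> variant filter, with one global seed.

Per-stage seeds are derived deterministically from the global seed by
hashing the stage name, so any stage can be re-run in isolation and the
whole report is byte-identical for identical config + seed. Every output
file carries the config hash and seed as a header comment.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import de as de_mod
from . import dynamics as dyn_mod
from . import preprocess as pp
from . import signatures as sig_mod
from . import wgs as wgs_mod
from ._utils import derive_seed
from .data_io import read_counts_triplet, read_gene_sets
from .simulate import SimConfig, generate_cohort, inject_variants

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""


@dataclass
class PipelineConfig:
    # inputs: either a simulation config or on-disk paths
    sim: Optional[SimConfig] = None
    counts_dir: Optional[str] = None
    metadata_path: Optional[str] = None
    annotation_path: Optional[str] = None
    gene_sets_path: Optional[str] = None
    variants_indolent: Optional[str] = None
    variants_active: Optional[str] = None
    # stage parameters (defaults mirror the per-module defaults)
    min_features: int = 250
    max_features: int = 4500
    max_mito: float = 0.20
    norm_scale: float = 1e4
    n_components: int = 15
    n_hvg: int = 2000
    k_neighbors: int = 20
    resolution: float = 1.5
    dyn_B: int = 10_000
    dyn_alpha: float = 0.05
    dyn_tau: float = 1.0
    de_min_frac: float = 0.01
    deg_alpha: float = 0.05
    deg_lfc: float = 0.5
    rec_B: int = 10_000
    rec_k: int = 2
    score_bins: int = 24
    score_ctrl: int = 100
    score_B: int = 10_000
    trajectory_genes: tuple = ("ATM",)
    seed: int = 0
    outdir: Optional[str] = None

    def config_hash(self) -> str:
        def canon(obj):
            if isinstance(obj, dict):
                return sorted((str(k), canon(v)) for k, v in obj.items())
            if isinstance(obj, (list, tuple, set, frozenset)):
                items = [canon(v) for v in obj]
                return sorted(items) if isinstance(obj, (set, frozenset)) else items
            return str(obj)

        payload = asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(repr(canon(payload)).encode()).hexdigest()[:16]


def _log(stage: str, t0: float, msg: str = "done") -> None:
    print(f"[{stage}] {msg} ({time.perf_counter() - t0:.1f}s)", file=sys.stderr)


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return (and optionally write) the run report."""
    cfg_hash = cfg.config_hash()
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg_hash, "seed": cfg.seed, "stages": {}}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    report["stages"][name] = {"status": "failed", "error": str(exc)}
                    if outdir:
                        (outdir / "report.partial.json").write_text(
                            json.dumps(report, sort_keys=True, indent=2, default=str)
                        )
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                _log(name, self.t0)
                return False

        return _Ctx()

    # ------------------------------------------------------------------ load
    with stage("load"):
        gene_sets = []
        variants = None
        truth = None
        if cfg.sim is not None:
            sim = cfg.sim
            if sim.seed != cfg.seed:
                from dataclasses import replace

                sim = replace(sim, seed=derive_seed(cfg.seed, "simulate"))
            m, cells, ann, truth = generate_cohort(sim)
            gene_sets = list(truth.signature_gene_sets)
            variants = inject_variants(sim, truth)
        else:
            if cfg.counts_dir is None or cfg.metadata_path is None:
                raise ValueError("need either a sim config or counts + metadata paths")
            m = read_counts_triplet(cfg.counts_dir)
            cells = pd.read_csv(cfg.metadata_path, sep="\t", comment="#")
            ann = (
                pd.read_csv(cfg.annotation_path, sep="\t", comment="#")
                if cfg.annotation_path
                else pd.DataFrame(
                    {"gene_id": m.gene_ids, "is_protein_coding": True,
                     "is_metabolic": False,
                     "is_mitochondrial": [g.startswith("MT-") for g in m.gene_ids]}
                )
            )
            if cfg.gene_sets_path:
                gene_sets = read_gene_sets(cfg.gene_sets_path)
            if cfg.variants_indolent and cfg.variants_active:
                from .data_io import read_variants

                variants = (read_variants(cfg.variants_indolent),
                            read_variants(cfg.variants_active))
        report["stages"]["load"] = {
            "n_cells": int(m.n_cells), "n_genes": int(m.n_genes),
            "n_gene_sets": len(gene_sets),
        }

    # -------------------------------------------------------------------- qc
    with stage("qc"):
        m_qc, qc_report = pp.qc_filter(
            m, ann, cfg.min_features, cfg.max_features, cfg.max_mito
        )
        keep = qc_report.table["kept"].to_numpy()
        cells = cells.loc[keep].reset_index(drop=True)
        report["stages"]["qc"] = {
            "n_cells_in": qc_report.n_cells_in,
            "n_cells_kept": qc_report.n_cells_kept,
        }
        if outdir:
            t = qc_report.table.copy()
            t["reasons"] = t["reasons"].map(",".join)
            _write_tsv(t, outdir / "qc_report.tsv", cfg_hash, cfg.seed, index=False)

    # ------------------------------------------------------------- normalize
    with stage("normalize"):
        m_norm = pp.normalize_log1p(m_qc, cfg.norm_scale)
        report["stages"]["normalize"] = {"scale": cfg.norm_scale}

    pair_patients = sorted(
        p for p, g in cells.groupby("patient_id")
        if {"indolent", "active"} <= set(g["timepoint"])
    )

    # ------------------------------------------------- per-pair clustering
    with stage("cluster"):
        cluster_labels = pd.Series(pd.NA, index=cells.index, dtype="Int64")
        for p in pair_patients:
            sel = (cells["patient_id"] == p).to_numpy()
            emb = pp.pca_embed(
                m_norm.subset_cells(sel), cfg.n_components, cfg.n_hvg,
                seed=derive_seed(cfg.seed, f"pca:{p}"),
            )
            labels = pp.snn_cluster(
                emb, cfg.k_neighbors, cfg.resolution,
                seed=derive_seed(cfg.seed, f"cluster:{p}"),
            )
            cluster_labels.loc[np.flatnonzero(sel)] = labels
        cells["snn_cluster"] = cluster_labels
        report["stages"]["cluster"] = {
            p: int(cells.loc[cells["patient_id"] == p, "snn_cluster"].nunique())
            for p in pair_patients
        }

    # --------------------------------------------------------------- dynamics
    with stage("dynamics"):
        shift_tables = {}
        for p in pair_patients:
            sub = cells[cells["patient_id"] == p]
            res = dyn_mod.proportion_shift_test(
                sub, clusters=sub["snn_cluster"].to_numpy(),
                B=cfg.dyn_B, seed=derive_seed(cfg.seed, f"dynamics:{p}"),
                alpha=cfg.dyn_alpha, tau=cfg.dyn_tau,
            )
            shift_tables[p] = res
            if outdir:
                _write_tsv(res, outdir / f"cluster_shift_{p}.tsv", cfg_hash, cfg.seed)
        report["stages"]["dynamics"] = {
            p: {
                "n_clusters": int(len(t)),
                "expanding": sorted(int(c) for c in t.index[t["class"] == "expanding"]),
                "shrinking": sorted(int(c) for c in t.index[t["class"] == "shrinking"]),
            }
            for p, t in shift_tables.items()
        }

    # --------------------------------------------------------------------- de
    with stage("de"):
        deg_sets, universes, de_tables = {}, {}, {}
        for p in pair_patients:
            sel = (cells["patient_id"] == p).to_numpy()
            sub_norm = m_norm.subset_cells(sel)
            sub_cells = cells[sel]
            gene_mask = de_mod.expression_fraction_filter(
                sub_norm, min_frac=cfg.de_min_frac
            )
            sub_norm = sub_norm.subset_genes(gene_mask)
            ga = (sub_cells["timepoint"] == "active").to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tab = de_mod.wilcoxon_de(
                    sub_norm, ga, ~ga,
                    alpha=cfg.deg_alpha, lfc_threshold=cfg.deg_lfc,
                )
            de_tables[p] = tab
            deg_sets[p] = set(tab.index[tab["is_deg"]])
            universes[p] = set(tab.index)
            if outdir:
                _write_tsv(tab, outdir / f"de_pair_{p}.tsv", cfg_hash, cfg.seed)
        report["stages"]["de"] = {
            p: {"n_tested": len(universes[p]), "n_deg": len(deg_sets[p])}
            for p in pair_patients
        }

    # -------------------------------------------------------------- recurrence
    with stage("recurrence"):
        if len(pair_patients) >= 2:
            rec = de_mod.recurrence_permutation_test(
                deg_sets, universes, B=cfg.rec_B,
                seed=derive_seed(cfg.seed, "recurrence"), k=cfg.rec_k,
            )
            report["stages"]["recurrence"] = {
                "observed_count_ge_k": rec.observed_count_ge_k,
                "k": rec.k,
                "p": rec.p,
                "histogram": {str(k): int(v) for k, v in rec.histogram.items()},
            }
            if outdir:
                _write_tsv(rec.histogram.to_frame(),
                           outdir / "recurrence_histogram.tsv", cfg_hash, cfg.seed)
        else:
            report["stages"]["recurrence"] = {"skipped": "fewer than 2 pairs"}

    # ------------------------------------------------- pseudobulk DE (dynamics)
    with stage("pseudobulk_de"):
        pb_summary = {}
        for p in pair_patients:
            shifts = shift_tables[p]
            classes = shifts["class"]
            if not {"expanding", "shrinking"} <= set(classes):
                pb_summary[p] = {"skipped": "needs both expanding and shrinking clusters"}
                continue
            sel = (cells["patient_id"] == p).to_numpy()
            sub_raw = m_qc.subset_cells(sel)
            sub_cells = cells[sel]
            moving = classes[classes != "stable"]
            cell_cl = sub_cells["snn_cluster"].to_numpy()
            in_moving = np.isin(cell_cl, moving.index.to_numpy())
            gene_mask = de_mod.expression_fraction_filter(
                sub_raw, min_frac=cfg.de_min_frac
            )
            pb = de_mod.pseudobulk_aggregate(
                sub_raw.subset_cells(in_moving).subset_genes(gene_mask),
                cell_cl[in_moving],
            )
            cond = classes.loc[pb.counts.index].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tab = de_mod.nb_lrt_de(pb, cond, alpha_deg=cfg.deg_alpha,
                                       lfc_threshold=cfg.deg_lfc)
            pb_summary[p] = {"n_tested": int(len(tab)),
                             "n_deg": int(tab["is_deg"].sum())}
            if outdir:
                _write_tsv(tab, outdir / f"pseudobulk_de_{p}.tsv", cfg_hash, cfg.seed)
        report["stages"]["pseudobulk_de"] = pb_summary

    # ------------------------------------------------------------------ scores
    with stage("scores"):
        score_summary = {}
        design = (
            cells.groupby("sample_id")
            .agg(patient=("patient_id", "first"), timepoint=("timepoint", "first"))
        )
        for gs in gene_sets:
            ms = sig_mod.module_score(
                m_norm, gs, cfg.score_bins, cfg.score_ctrl,
                seed=derive_seed(cfg.seed, f"score:{gs.name}"),
            )
            per_sample = ms.scores.groupby(cells.set_index("cell_id")["sample_id"]).mean()
            p_val = sig_mod.sample_mean_permutation_test(
                per_sample, design, B=cfg.score_B,
                seed=derive_seed(cfg.seed, f"scoretest:{gs.name}"),
            )
            score_summary[gs.name] = {
                "sample_means": {s: float(v) for s, v in per_sample.items()},
                "p_indolent_vs_active": p_val,
            }
        frac = sig_mod.metabolic_fraction(
            m_qc, ann, per="sample", samples=cells["sample_id"].to_numpy()
        )
        frac_p = sig_mod.sample_mean_permutation_test(
            frac, design, B=cfg.score_B,
            seed=derive_seed(cfg.seed, "scoretest:metabolic"),
        )
        score_summary["metabolic_fraction"] = {
            "sample_means": {s: float(v) for s, v in frac.items()},
            "p_indolent_vs_active": frac_p,
        }
        report["stages"]["scores"] = score_summary

    # --------------------------------------------------------------------- wgs
    with stage("wgs"):
        if variants is not None:
            v_ind, v_act = variants
            f_ind = wgs_mod.filter_short_variants(v_ind)
            f_act = wgs_mod.filter_short_variants(v_act)
            traj = wgs_mod.vaf_trajectory(f_ind, f_act, list(cfg.trajectory_genes))
            report["stages"]["wgs"] = {
                "n_pass_indolent": int((f_ind["verdict"] == "pass").sum()),
                "n_pass_active": int((f_act["verdict"] == "pass").sum()),
                "trajectory": {
                    g: {
                        "mean_vaf_indolent": float(r["mean_vaf_indolent"]),
                        "mean_vaf_active": float(r["mean_vaf_active"]),
                        "delta": float(r["delta"]),
                    }
                    for g, r in traj.iterrows()
                    if not np.isnan(r["mean_vaf_indolent"])
                },
            }
            if outdir:
                _write_tsv(traj, outdir / "vaf_trajectory.tsv", cfg_hash, cfg.seed)
        else:
            report["stages"]["wgs"] = {"skipped": "no variants provided"}

    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2, default=str)
        )
    return report
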