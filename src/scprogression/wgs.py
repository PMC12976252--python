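"""Tumor-only somatic short-variant retention filter and VAF trajectories.

A variant is retained when all of the following hold: VAF >= 5%, depth >=
10 reads with >= 3 alt-supporting reads, population allele frequency <=
0.01, dbSNP MAF <= 0.05, and TOPMed MAF <= 0.05. Population-frequency
annotations absent from the input pass their criterion (tumor-only calling
leaves many sites unannotated). Longitudinal trajectories compare per-gene
mean VAFs of allele-matched variants between the indolent and active time
points; a variant seen at only one time point contributes 0 at the other
and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FilterConfig", "filter_short_variants", "vaf_trajectory"]

LOW_VAF = "low_vaf"
LOW_DEPTH = "low_depth"
LOW_ALT_READS = "low_alt_reads"
HIGH_POP_AF = "high_pop_af"
HIGH_DBSNP_MAF = "high_dbsnp_maf"
HIGH_TOPMED_MAF = "high_topmed_maf"


@dataclass(frozen=True)
class FilterConfig:
    min_vaf: float = 0.05
    min_depth: int = 10
    min_alt_reads: int = 3
    max_pop_af: float = 0.01
    max_dbsnp_maf: float = 0.05
    max_topmed_maf: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.min_vaf <= 1):
            raise ValueError("min_vaf must be in [0, 1]")
        if self.min_depth < 0 or self.min_alt_reads < 0:
            raise ValueError("depth thresholds must be non-negative")
        for f in (self.max_pop_af, self.max_dbsnp_maf, self.max_topmed_maf):
            if not (0 <= f <= 1):
                raise ValueError("frequency thresholds must be in [0, 1]")


def filter_short_variants(
    variants: pd.DataFrame, cfg: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Annotate each variant with a pass/fail verdict and failure reasons.

    All thresholds are inclusive on the passing side (a variant exactly at
    VAF 0.05, depth 10, 3 alt reads passes). Missing population-frequency
    values are treated as 0 and pass those criteria. Failing records list
    every violated criterion; the filter is monotone in each threshold and
    idempotent.
    """
    v = variants.copy()
    vaf = v["vaf"].to_numpy(dtype=float)
    depth = v["depth"].to_numpy(dtype=float)
    alt = v["alt_reads"].to_numpy(dtype=float)

    def freq(col: str) -> np.ndarray:
        if col not in v:
            return np.zeros(len(v))
        return np.nan_to_num(v[col].to_numpy(dtype=float), nan=0.0)

    checks = [
        (LOW_VAF, vaf < cfg.min_vaf),
        (LOW_DEPTH, depth < cfg.min_depth),
        (LOW_ALT_READS, alt < cfg.min_alt_reads),
        (HIGH_POP_AF, freq("pop_af") > cfg.max_pop_af),
        (HIGH_DBSNP_MAF, freq("dbsnp_maf") > cfg.max_dbsnp_maf),
        (HIGH_TOPMED_MAF, freq("topmed_maf") > cfg.max_topmed_maf),
    ]
    reasons = [[] for _ in range(len(v))]
    fail = np.zeros(len(v), dtype=bool)
    for code, bad in checks:
        fail |= bad
        for i in np.flatnonzero(bad):
            reasons[i].append(code)
    v["verdict"] = np.where(fail, "fail", "pass")
    v["reasons"] = reasons
    return v


ALLELE_KEY = ["chrom", "pos", "ref", "alt"]


def vaf_trajectory(
    v_indolent: pd.DataFrame,
    v_active: pd.DataFrame,
    gene_list,
) -> pd.DataFrame:
    """Per-gene mean VAF at each time point and the active-indolent delta.

    Inputs should already carry filter verdicts (only passing variants are
    used when a ``verdict`` column is present). Variants are matched on
    the exact (chrom, pos, ref, alt) key; a variant present at only one
    time point contributes 0 at the missing one and is flagged
    ``emergent`` (active only) or ``vanishing`` (indolent only).
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("gene_list must not be empty")

    def prep(df: pd.DataFrame) -> pd.DataFrame:
        if "verdict" in df:
            df = df[df["verdict"] == "pass"]
        return df[ALLELE_KEY + ["vaf", "gene"]]

    vi = prep(v_indolent)
    va = prep(v_active)
    merged = vi.merge(va, on=ALLELE_KEY, how="outer", suffixes=("_ind", "_act"))
    merged["gene"] = merged["gene_ind"].where(merged["gene_ind"].notna(),
                                              merged["gene_act"])
    merged["flag"] = np.select(
        [merged["vaf_ind"].isna(), merged["vaf_act"].isna()],
        ["emergent", "vanishing"],
        default="shared",
    )
    merged["vaf_ind"] = merged["vaf_ind"].fillna(0.0)
    merged["vaf_act"] = merged["vaf_act"].fillna(0.0)

    rows = []
    for gene in gene_list:
        sub = merged[merged["gene"] == gene]
        if len(sub) == 0:
            rows.append((gene, np.nan, np.nan, np.nan, 0, ""))
            continue
        mi = float(sub["vaf_ind"].mean())
        ma = float(sub["vaf_act"].mean())
        flags = ",".join(sorted(set(sub["flag"]) - {"shared"}))
        rows.append((gene, mi, ma, ma - mi, len(sub), flags))
    return pd.DataFrame(
        rows,
        columns=["gene", "mean_vaf_indolent", "mean_vaf_active", "delta",
                 "n_variants", "flags"],
    ).set_index("gene")
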