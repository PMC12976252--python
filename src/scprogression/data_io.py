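"""Core containers and readers/writers for the formats the pipeline touches.

The in-memory model is deliberately small: a sparse cells x genes
:class:`CountMatrix`, a per-cell metadata table, a gene annotation table,
named gene sets, and a per-allele variant table. On-disk formats are the
10x-style MatrixMarket triplet (matrix.mtx + features.tsv + barcodes.tsv,
genes x cells on disk, transposed to cells x genes on read), MSigDB GMT,
plain TSV, and VCF 4.x.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "GeneSet",
    "FormatError",
    "read_counts_triplet",
    "write_counts_triplet",
    "read_gene_sets",
    "write_gene_sets",
    "read_variants",
    "write_variants_vcf",
    "make_cell_table",
    "VARIANT_COLUMNS",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


RAW = "raw"
NORMALIZED = "normalized"


@dataclass
class CountMatrix:
    """Sparse cells x genes expression matrix with a layer flag.

    The ``raw`` layer holds non-negative integer UMI counts; the
    ``normalized`` layer holds non-negative reals (library-size scaled,
    log1p transformed). Gene identity is by symbol; duplicate symbols must
    be disambiguated before construction.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    layer: str = RAW

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.layer not in (RAW, NORMALIZED):
            raise ValueError(f"unknown layer {self.layer!r}")
        n_cells, n_genes = self.values.shape
        if n_genes != len(self.gene_ids):
            raise FormatError(
                f"matrix has {n_genes} gene columns but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise FormatError(
                f"matrix has {n_cells} cell rows but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative matrix entries")
        if self.layer == RAW and self.values.nnz:
            if not np.allclose(self.values.data, np.round(self.values.data)):
                raise FormatError("raw layer contains non-integer values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Column indices of ``genes`` (genes absent from the matrix are skipped)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            self.values[idx], self.gene_ids, self.cell_ids[idx], layer=self.layer
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            self.values[:, idx], self.gene_ids[idx], self.cell_ids, layer=self.layer
        )


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (order-preserving, no duplicates)."""

    name: str
    genes: tuple

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        seen = set()
        deduped = tuple(g for g in self.genes if not (g in seen or seen.add(g)))
        object.__setattr__(self, "genes", deduped)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def _dedupe_symbols(symbols: Sequence[str]) -> list:
    """Disambiguate duplicate gene symbols by suffixing .1, .2 in file order."""
    counts: dict = {}
    out = []
    for s in symbols:
        k = counts.get(s, 0)
        out.append(s if k == 0 else f"{s}.{k}")
        counts[s] = k + 1
    return out


def read_counts_triplet(directory: os.PathLike | str) -> CountMatrix:
    """Read a 10x-style triplet directory into a raw cells x genes CountMatrix.

    Expects ``matrix.mtx`` (genes x cells, MatrixMarket coordinate),
    ``features.tsv`` (gene id and/or symbol columns) and ``barcodes.tsv``.
    The symbol column (second column when present) names genes; duplicate
    symbols get deterministic ``.1``, ``.2`` suffixes in file order.
    """
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    feat_path = directory / "features.tsv"
    bc_path = directory / "barcodes.tsv"
    for p in (mtx_path, feat_path, bc_path):
        if not p.exists():
            raise FormatError(f"missing {p.name} in {directory}")
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"unreadable MatrixMarket file: {exc}") from exc
    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].tolist()
    symbol_col = 1 if feats.shape[1] >= 2 else 0
    symbols = _dedupe_symbols(feats[symbol_col].tolist())
    n_genes, n_cells = mat.shape
    if n_genes != len(symbols):
        raise FormatError(
            f"MTX header says {n_genes} genes but features.tsv has {len(symbols)}"
        )
    if n_cells != len(barcodes):
        raise FormatError(
            f"MTX header says {n_cells} cells but barcodes.tsv has {len(barcodes)}"
        )
    mat = sp.coo_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("raw count matrix contains non-integer values")
    values = sp.csr_matrix(mat.T.astype(np.int64))
    return CountMatrix(values, np.array(symbols, dtype=object),
                       np.array(barcodes, dtype=object), layer=RAW)


def write_counts_triplet(m: CountMatrix, directory: os.PathLike | str) -> None:
    """Write a raw CountMatrix as a 10x-style triplet (genes x cells on disk)."""
    if m.layer != RAW:
        raise ValueError("write_counts_triplet requires the raw layer")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    on_disk = sp.coo_matrix(m.values.T.astype(np.int64))
    scipy.io.mmwrite(str(directory / "matrix.mtx"), on_disk, field="integer")
    feats = pd.DataFrame(
        {0: m.gene_ids, 1: m.gene_ids, 2: "Gene Expression"}
    )
    feats.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_gene_sets(path: os.PathLike | str) -> list:
    """Parse a GMT file: one gene set per line, ``name<TAB>description<TAB>genes...``."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet(name, tuple(genes)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "depth", "alt_reads", "vaf",
    "pop_af", "dbsnp_maf", "topmed_maf", "gene",
]


def read_variants(
    path: os.PathLike | str,
    pop_af_key: str = "POPAF",
    dbsnp_key: str = "DBSNP_MAF",
    topmed_key: str = "TOPMED_MAF",
    gene_key: str = "GENE",
) -> pd.DataFrame:
    """Read somatic short variants from a VCF into a per-allele table.

    Multi-allelic sites are split into one row per ALT allele. Depth and
    alt-supporting reads come from the first sample's AD (DP as fallback
    total); VAF = alt_reads / depth. Population-frequency INFO keys are
    configurable because annotation dialects differ; absent keys yield NaN
    (the downstream filter treats absent as 0).
    """
    import cyvcf2

    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable VCF {path}: {exc}") from exc
    rows = []
    try:
        for rec in vcf:
            def _fmt(key):
                try:
                    return rec.format(key)
                except KeyError:
                    return None

            ad = _fmt("AD")
            dp = _fmt("DP")
            if ad is None and dp is None:
                raise FormatError(
                    f"{rec.CHROM}:{rec.POS}: neither AD nor DP present"
                )
            n_alt = len(rec.ALT)
            for ai, alt in enumerate(rec.ALT):
                if ad is not None:
                    sample_ad = np.asarray(ad[0], dtype=np.int64)
                    alt_reads = int(sample_ad[ai + 1])
                    depth = int(sample_ad.sum())
                    if dp is not None:
                        depth = max(depth, int(np.asarray(dp[0]).ravel()[0]))
                else:
                    depth = int(np.asarray(dp[0]).ravel()[0])
                    alt_reads = 0
                if alt_reads > depth:
                    raise FormatError(
                        f"{rec.CHROM}:{rec.POS}: alt reads {alt_reads} exceed depth {depth}"
                    )
                vaf = alt_reads / depth if depth > 0 else 0.0

                def _info_freq(key: str):
                    v = rec.INFO.get(key)
                    if v is None:
                        return np.nan
                    if isinstance(v, (tuple, list)):
                        v = v[ai] if ai < len(v) else v[0]
                    # htslib hands Float INFO back as float32; recover the
                    # decimal the file carried so 0.05 stays exactly 0.05
                    return float(f"{float(v):.6g}")

                gene = rec.INFO.get(gene_key)
                rows.append(
                    {
                        "chrom": rec.CHROM,
                        "pos": rec.POS,
                        "ref": rec.REF,
                        "alt": alt,
                        "depth": depth,
                        "alt_reads": alt_reads,
                        "vaf": vaf,
                        "pop_af": _info_freq(pop_af_key),
                        "dbsnp_maf": _info_freq(dbsnp_key),
                        "topmed_maf": _info_freq(topmed_key),
                        "gene": gene,
                        "_n_alt": n_alt,
                    }
                )
    finally:
        vcf.close()
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["_n_alt"])
    return df.drop(columns=["_n_alt"])


def write_variants_vcf(
    variants: pd.DataFrame,
    path: os.PathLike | str,
    sample_name: str = "TUMOR",
    pop_af_key: str = "POPAF",
    dbsnp_key: str = "DBSNP_MAF",
    topmed_key: str = "TOPMED_MAF",
    gene_key: str = "GENE",
) -> None:
    """Write a variant table as a minimal single-sample VCF 4.2 with AD/DP."""
    contigs = list(dict.fromkeys(variants["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(f'##INFO=<ID={pop_af_key},Number=1,Type=Float,Description="Population allele frequency">\n')
        fh.write(f'##INFO=<ID={dbsnp_key},Number=1,Type=Float,Description="dbSNP minor allele frequency">\n')
        fh.write(f'##INFO=<ID={topmed_key},Number=1,Type=Float,Description="TOPMed minor allele frequency">\n')
        fh.write(f'##INFO=<ID={gene_key},Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + sample_name
            + "\n"
        )
        for _, r in variants.iterrows():
            info = []
            for key, col in [
                (pop_af_key, "pop_af"),
                (dbsnp_key, "dbsnp_maf"),
                (topmed_key, "topmed_maf"),
            ]:
                v = r.get(col)
                if v is not None and not pd.isna(v):
                    info.append(f"{key}={float(v):.6g}")
            g = r.get("gene")
            if g is not None and not pd.isna(g):
                info.append(f"{gene_key}={g}")
            depth = int(r["depth"])
            alt_reads = int(r["alt_reads"])
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t"
                f"{';'.join(info) if info else '.'}\tAD:DP\t"
                f"{depth - alt_reads},{alt_reads}:{depth}\n"
            )


def make_cell_table(
    cell_ids: Sequence[str],
    patient_id: Sequence[str],
    sample_id: Sequence[str],
    timepoint: Sequence[str],
    cell_type=None,
    cluster=None,
    n_features=None,
    pct_mito=None,
) -> pd.DataFrame:
    """Assemble a validated per-cell metadata table.

    Enforces unique cell ids, known time-point labels, and that each
    sample id maps to exactly one (patient, timepoint).
    """
    df = pd.DataFrame(
        {
            "cell_id": np.asarray(cell_ids, dtype=object),
            "patient_id": np.asarray(patient_id, dtype=object),
            "sample_id": np.asarray(sample_id, dtype=object),
            "timepoint": np.asarray(timepoint, dtype=object),
        }
    )
    if df["cell_id"].duplicated().any():
        raise FormatError("duplicate cell ids in cell table")
    bad = set(df["timepoint"]) - {"indolent", "active", "healthy"}
    if bad:
        raise FormatError(f"unknown timepoint labels: {sorted(bad)}")
    per_sample = df.groupby("sample_id")[["patient_id", "timepoint"]].nunique()
    if (per_sample > 1).any().any():
        raise FormatError("a sample_id maps to more than one (patient, timepoint)")
    df["cell_type"] = cell_type if cell_type is not None else pd.NA
    df["cluster"] = cluster if cluster is not None else pd.NA
    if n_features is not None:
        df["n_features"] = np.asarray(n_features, dtype=int)
    if pct_mito is not None:
        pm = np.asarray(pct_mito, dtype=float)
        if pm.size and (pm.min() < 0 or pm.max() > 1):
            raise FormatError("pct_mito outside [0, 1]")
        df["pct_mito"] = pm
    return df
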