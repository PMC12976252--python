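"""Per-pair DE, cross-patient DEG recurrence, and pseudobulk DE.

Stage 1: per pair, Wilcoxon rank-sum DE between active and indolent
T cells on the 1%-expressed gene universe (DEG = adjusted p < 0.05 and
|log2FC| >= 0.5). Stage 2: a gene-label permutation test asks whether the
number of genes recurring as DEGs in >= 2 pairs exceeds chance. Stage 3:
pseudobulk NB likelihood-ratio DE between expanding and shrinking
clusters of each pair. Writes results/de_<patient>.tsv,
results/recurrence.tsv and results/pseudobulk_de_<patient>.tsv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common as config  # noqa: E402

import numpy as np  # noqa: E402

from scprogression import (  # noqa: E402
    expression_fraction_filter,
    nb_lrt_de,
    normalize_log1p,
    pseudobulk_aggregate,
    qc_filter,
    recurrence_permutation_test,
    wilcoxon_de,
)
from scprogression._utils import derive_seed  # noqa: E402
from scprogression.data_io import read_counts_triplet  # noqa: E402


def main() -> None:
    m = read_counts_triplet(config.COHORT_DIR / "counts")
    ann = pd.read_csv(config.COHORT_DIR / "annotation.tsv", sep="\t")
    cells = pd.read_csv(config.RESULTS / "clusters.tsv", sep="\t")
    shifts = pd.read_csv(config.RESULTS / "cluster_shifts.tsv", sep="\t")
    truth = pd.read_csv(config.COHORT_DIR / "truth_degs.tsv", sep="\t")

    m_qc, rep = qc_filter(m, ann)
    assert rep.n_cells_kept == len(cells), "run 02_preprocess_cluster.py first"
    norm = normalize_log1p(m_qc)

    deg_sets, universes = {}, {}
    for p in sorted(cells["patient_id"].unique()):
        sel = (cells["patient_id"] == p).to_numpy()
        sub = norm.subset_cells(sel)
        sub = sub.subset_genes(expression_fraction_filter(sub, min_frac=0.01))
        ga = (cells.loc[sel, "timepoint"] == "active").to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = wilcoxon_de(sub, ga, ~ga)
        tab.to_csv(config.RESULTS / f"de_{p}.tsv", sep="\t")
        deg_sets[p] = set(tab.index[tab["is_deg"]])
        universes[p] = set(tab.index)
        planted = set(truth.loc[truth["patient_id"] == p, "gene"])
        found = len(deg_sets[p] & planted)
        print(f"{p}: {len(deg_sets[p])} DEGs of {len(universes[p])} tested; "
              f"{found}/{len(planted)} planted DEGs recovered")

    rec = recurrence_permutation_test(
        deg_sets, universes, B=config.REC_B,
        seed=derive_seed(config.GLOBAL_SEED, "recurrence"),
    )
    union = int(rec.histogram.sum())
    shared = int(rec.histogram[rec.histogram.index >= 2].sum())
    print(f"recurrence: {shared}/{union} DEGs "
          f"({100 * shared / max(union, 1):.1f}%) found in >=2 pairs, "
          f"one-sided permutation p = {rec.p:.2e} (B={rec.B})")
    rec.histogram.to_frame().assign(p=rec.p).to_csv(
        config.RESULTS / "recurrence.tsv", sep="\t"
    )

    for p in sorted(cells["patient_id"].unique()):
        sh = shifts[shifts["patient_id"] == p].set_index("cluster")
        moving = sh[sh["class"] != "stable"]
        if not {"expanding", "shrinking"} <= set(moving["class"]):
            print(f"{p}: skipped pseudobulk DE (needs both cluster classes)")
            continue
        sel = (cells["patient_id"] == p).to_numpy()
        sub_raw = m_qc.subset_cells(sel)
        cl = cells.loc[sel, "snn_cluster"].to_numpy()
        in_moving = np.isin(cl, moving.index.to_numpy())
        sub_raw = sub_raw.subset_genes(
            expression_fraction_filter(sub_raw, min_frac=0.01)
        )
        pb = pseudobulk_aggregate(sub_raw.subset_cells(in_moving), cl[in_moving])
        cond = moving.loc[pb.counts.index, "class"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = nb_lrt_de(pb, cond)
        tab.to_csv(config.RESULTS / f"pseudobulk_de_{p}.tsv", sep="\t")
        print(f"{p}: pseudobulk expanding-vs-shrinking DE: "
              f"{int(tab['is_deg'].sum())} DEGs of {len(tab)}")


if __name__ == "__main__":
    main()
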