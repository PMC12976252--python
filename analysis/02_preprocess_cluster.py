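"""Quality-filter the cohort, normalize, and cluster each patient pair.

Reads results/cohort/, applies the 250-4500 feature / <20% mitochondrial
QC gates, library-size log1p normalization, per-pair PCA (top 15
components of the 2000 most variable genes) and SNN modularity
clustering. Writes the kept-cell table with SNN labels to
results/clusters.tsv and prints per-stage summaries.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common as config  # noqa: E402

import numpy as np  # noqa: E402

from scprogression import normalize_log1p, pca_embed, qc_filter, snn_cluster  # noqa: E402
from scprogression._utils import derive_seed  # noqa: E402
from scprogression.data_io import read_counts_triplet  # noqa: E402


def main() -> None:
    cohort = config.COHORT_DIR
    m = read_counts_triplet(cohort / "counts")
    cells = pd.read_csv(cohort / "cells.tsv", sep="\t")
    ann = pd.read_csv(cohort / "annotation.tsv", sep="\t")

    m_qc, report = qc_filter(m, ann)
    cells = cells.loc[report.table["kept"].to_numpy()].reset_index(drop=True)
    print(f"QC: kept {report.n_cells_kept}/{report.n_cells_in} cells "
          f"({100 * report.n_cells_kept / report.n_cells_in:.1f}%)")

    norm = normalize_log1p(m_qc)
    labels = pd.Series(pd.NA, index=cells.index, dtype="Int64")
    for p in sorted(cells["patient_id"].unique()):
        sel = (cells["patient_id"] == p).to_numpy()
        emb = pca_embed(norm.subset_cells(sel),
                        seed=derive_seed(config.GLOBAL_SEED, f"pca:{p}"))
        lab = snn_cluster(emb, resolution=config.RESOLUTION,
                          seed=derive_seed(config.GLOBAL_SEED, f"cluster:{p}"))
        labels.loc[np.flatnonzero(sel)] = lab
        print(f"  {p}: {lab.max() + 1} SNN clusters over {sel.sum()} cells")
    cells["snn_cluster"] = labels
    out = config.RESULTS / "clusters.tsv"
    cells.to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
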