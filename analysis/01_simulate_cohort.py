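"""Simulate the paired two-time-point cohort and write it to disk.

Writes the 10x-style count triplet, cell metadata, gene annotation, the
planted-truth tables, signature gene sets (GMT), and the two somatic
variant VCFs under results/cohort/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common as config  # noqa: E402

from scprogression import generate_cohort, inject_variants  # noqa: E402
from scprogression.data_io import (  # noqa: E402
    write_counts_triplet,
    write_gene_sets,
    write_variants_vcf,
)


def main() -> None:
    out = config.COHORT_DIR
    out.mkdir(parents=True, exist_ok=True)
    m, cells, ann, truth = generate_cohort(config.SIM)

    write_counts_triplet(m, out / "counts")
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
    truth.deg_table.to_csv(out / "truth_degs.tsv", sep="\t", index=False)
    truth.cluster_props.to_csv(out / "truth_cluster_props.tsv", sep="\t",
                               index=False)
    write_gene_sets(truth.signature_gene_sets, out / "signatures.gmt")

    v_ind, v_act = inject_variants(config.SIM, truth)
    write_variants_vcf(v_ind, out / "variants_indolent.vcf")
    write_variants_vcf(v_act, out / "variants_active.vcf")

    n_planted = len(truth.expanding_clusters) + len(truth.shrinking_clusters)
    print(f"cohort: {m.n_cells} cells x {m.n_genes} genes over "
          f"{config.SIM.n_patients} paired patients")
    print(f"planted: {n_planted} shifting clusters, "
          f"{len(truth.recurrent_genes)} recurrent + "
          f"{len(truth.private_genes)} private DEGs, "
          f"{len(truth.signature_gene_sets)} signature sets")
    print(f"wrote fixtures to {out}")


if __name__ == "__main__":
    main()
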