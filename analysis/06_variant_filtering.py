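"""Filter the somatic short variants and trace VAF trajectories.

Applies the retention filter (VAF >= 5%, depth >= 10 with >= 3 alt reads,
population AF <= 0.01, dbSNP/TOPMed MAF <= 0.05) to both time points and
compares per-gene mean VAFs of allele-matched variants, highlighting the
planted ATM outgrowth against the stable JAK/STAT subclones. Writes
results/variant_verdicts.tsv and results/vaf_trajectory.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common as config  # noqa: E402

from scprogression.data_io import read_variants  # noqa: E402
from scprogression.wgs import filter_short_variants, vaf_trajectory  # noqa: E402


def main() -> None:
    v_ind = filter_short_variants(
        read_variants(config.COHORT_DIR / "variants_indolent.vcf")
    )
    v_act = filter_short_variants(
        read_variants(config.COHORT_DIR / "variants_active.vcf")
    )
    for name, v in (("indolent", v_ind), ("active", v_act)):
        n_pass = int((v["verdict"] == "pass").sum())
        print(f"{name}: {n_pass}/{len(v)} variants pass the retention filter")
    verdicts = pd.concat(
        [v_ind.assign(timepoint="indolent"), v_act.assign(timepoint="active")]
    )
    verdicts["reasons"] = verdicts["reasons"].map(",".join)
    verdicts.to_csv(config.RESULTS / "variant_verdicts.tsv", sep="\t",
                    index=False)

    genes = sorted(set(v_ind["gene"].dropna()))
    traj = vaf_trajectory(v_ind, v_act, genes)
    traj.to_csv(config.RESULTS / "vaf_trajectory.tsv", sep="\t")
    for gene, row in traj.iterrows():
        if pd.isna(row["mean_vaf_indolent"]):
            continue
        print(f"{gene}: mean VAF {100 * row['mean_vaf_indolent']:.2f}% -> "
              f"{100 * row['mean_vaf_active']:.2f}% "
              f"(delta {100 * row['delta']:+.2f} points, "
              f"{int(row['n_variants'])} variants)")


if __name__ == "__main__":
    main()
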