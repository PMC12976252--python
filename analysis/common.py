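"""Shared settings for the analysis drivers.

A desk-scale paired cohort: 3 patients sampled at the indolent and the
active stage, 1,500 cells per sample, 3,000 genes, 8 subclusters per
patient of which one quadruples and one quarters its proportion between
time points. All drivers derive their stage seeds from GLOBAL_SEED.
"""

from pathlib import Path

from scprogression import SimConfig
from scprogression.simulate import SignatureSpec

GLOBAL_SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"
COHORT_DIR = RESULTS / "cohort"

SIM = SimConfig(
    n_patients=3,
    cells_per_sample=1500,
    n_genes=3000,
    n_clusters_per_patient=8,
    n_recurrent_degs=30,
    n_private_degs=45,
    n_markers_per_cluster=25,
    marker_log2fc=2.5,
    deg_log2fc=1.0,
    signature_sets=[
        SignatureSpec("MYC_LIKE_TARGETS", n_genes=40,
                      multipliers={"expanding": 2.0}),
        SignatureSpec("OXPHOS_LIKE", n_genes=40,
                      multipliers={"expanding": 1.6}),
    ],
    seed=GLOBAL_SEED,
)

RESOLUTION = 1.0
DYN_B = 5000
REC_B = 10_000
SCORE_B = 10_000
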