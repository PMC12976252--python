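"""Recovery metrics tying planted simulation truth to pipeline results.

These helpers quantify how well each analysis stage recovers what the
synthetic cohort planted: expanding/shrinking cluster calls against the
planted cluster dynamics (via majority-vote mapping of SNN clusters onto
true clusters), permutation-test calibration on null pairs, and
classification power on planted proportion shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import dynamics as dyn
from . import preprocess as pp
from ._utils import derive_seed
from .data_io import CountMatrix
from .simulate import SimTruth, simulate_composition_pair

__all__ = [
    "ClusterRecovery",
    "cluster_recovery",
    "dynamics_type1_rate",
    "dynamics_power",
]


@dataclass
class ClusterRecovery:
    detected_expanding: set  # {(patient, true_cluster)}
    detected_shrinking: set
    true_expanding: set
    true_shrinking: set

    @property
    def sensitivity(self) -> float:
        truth = self.true_expanding | self.true_shrinking
        if not truth:
            return float("nan")
        hits = len(self.detected_expanding & self.true_expanding) + len(
            self.detected_shrinking & self.true_shrinking
        )
        return hits / len(truth)

    @property
    def exact_match(self) -> bool:
        return (self.detected_expanding == self.true_expanding
                and self.detected_shrinking == self.true_shrinking)

    @property
    def n_false_calls(self) -> int:
        return len(self.detected_expanding - self.true_expanding) + len(
            self.detected_shrinking - self.true_shrinking
        )


def cluster_recovery(
    norm: CountMatrix,
    cells: pd.DataFrame,
    truth: SimTruth,
    seed: int,
    resolution: float = 1.0,
    B: int = 2000,
    n_components: int = 15,
    n_hvg: int = 2000,
    k_neighbors: int = 20,
    alpha: float = 0.05,
    tau: float = 1.0,
) -> ClusterRecovery:
    """Re-cluster each pair, classify shifts, and map calls onto true clusters.

    A true (planted) cluster counts as detected expanding/shrinking when
    the majority of its cells fall into SNN clusters carrying that call.
    Seeds are derived per stage exactly as the pipeline derives them.
    """
    detected_exp, detected_shr = set(), set()
    for p in sorted(cells["patient_id"].unique()):
        sel = (cells["patient_id"] == p).to_numpy()
        emb = pp.pca_embed(
            norm.subset_cells(sel), n_components, n_hvg,
            seed=derive_seed(seed, f"pca:{p}"),
        )
        labels = pp.snn_cluster(
            emb, k_neighbors, resolution, seed=derive_seed(seed, f"cluster:{p}")
        )
        sub = cells[sel]
        res = dyn.proportion_shift_test(
            sub, clusters=labels, B=B,
            seed=derive_seed(seed, f"dynamics:{p}"), alpha=alpha, tau=tau,
        )
        call_of_label = res["class"]
        df = pd.DataFrame({"true": sub["cluster"].to_numpy(), "snn": labels})
        df["call"] = call_of_label.loc[df["snn"]].to_numpy()
        for t_cl, grp in df.groupby("true"):
            share = grp["call"].value_counts(normalize=True)
            if share.get("expanding", 0) > 0.5:
                detected_exp.add((p, int(t_cl)))
            if share.get("shrinking", 0) > 0.5:
                detected_shr.add((p, int(t_cl)))
    return ClusterRecovery(
        detected_exp, detected_shr,
        set(truth.expanding_clusters), set(truth.shrinking_clusters),
    )


def dynamics_type1_rate(
    n_pairs: int = 500,
    n_cells: int = 2000,
    n_clusters: int = 8,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Per-cluster rejection rate of the shift test on exchangeable pairs."""
    rejections = 0
    total = 0
    for s in range(n_pairs):
        pair = simulate_composition_pair(
            n_cells, n_clusters, planted=None, seed=seed * 100_003 + s
        )
        res = dyn.proportion_shift_test(pair, B=B, seed=seed + s)
        rejections += int((res["p_perm"] < alpha).sum())
        total += len(res)
    return rejections / total


def dynamics_power(
    n_pairs: int = 100,
    n_cells: int = 3000,
    n_clusters: int = 8,
    delta: float = 2.0,
    B: int = 1000,
    seed: int = 0,
) -> tuple:
    """(sensitivity, misclassification rate) on planted four-fold shifts.

    Each simulated pair plants one expanding (+delta) and one shrinking
    (-delta) cluster; the remaining clusters hold exactly equal
    proportions at both time points.
    """
    hits = 0
    false_calls = 0
    n_planted = 0
    n_stable = 0
    for s in range(n_pairs):
        pair = simulate_composition_pair(
            n_cells, n_clusters, planted={0: delta, 1: -delta},
            seed=seed * 100_003 + s,
        )
        res = dyn.proportion_shift_test(pair, B=B, seed=seed + s)
        hits += int(res.loc[0, "class"] == "expanding")
        hits += int(res.loc[1, "class"] == "shrinking")
        n_planted += 2
        stable_idx = [c for c in res.index if c >= 2]
        false_calls += int((res.loc[stable_idx, "class"] != "stable").sum())
        # planted clusters called in the wrong direction also count as errors
        false_calls += int(res.loc[0, "class"] == "shrinking")
        false_calls += int(res.loc[1, "class"] == "expanding")
        n_stable += len(stable_idx)
    return hits / n_planted, false_calls / (n_planted + n_stable)
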