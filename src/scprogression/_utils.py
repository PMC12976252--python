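"""Shared numerical helpers: FDR adjustment and seeded RNG derivation."""

from __future__ import annotations

import hashlib

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "derive_seed", "rng_for"]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed (< 2**31) from a global seed."""
    h = hashlib.sha256(f"{int(global_seed)}::{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def rng_for(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(global_seed, stage))
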