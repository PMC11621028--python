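"""Conversion of latent (RDR, BAF) states into allele-specific integer copies.

A state with RDR mu and BAF p is mapped to the integer pair (a, b) of
A-haplotype and B-haplotype copies minimizing

    ((a + b) / gamma - mu)^2 + w_baf * (b / (a + b) - p)^2

over 0 <= a, b <= max_cn with a + b >= 1, where gamma is the ploidy scale
(total copies corresponding to RDR 1).  gamma is selected from a candidate
grid by the total, occupancy-weighted, error.  Homozygous deletion
(a = b = 0) is excluded: an RDR of 0 is not reliably measurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clones import CloneModel

__all__ = ["IntegerCN", "assign_integer_cn", "classify_events"]

DEFAULT_PLOIDY_GRID = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass
class IntegerCN:
    A: np.ndarray  # bin x clone A-haplotype copies
    B: np.ndarray  # bin x clone B-haplotype copies
    ploidy_scale: float  # copies per unit RDR (gamma)
    state_A: np.ndarray  # per-state A copies under the chosen gamma
    state_B: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.A + self.B


def _pairs(max_cn: int) -> np.ndarray:
    return np.array(
        [(a, b) for a in range(max_cn + 1) for b in range(max_cn + 1) if a + b >= 1]
    )


def assign_integer_cn(
    mu_k: np.ndarray,
    p_k: np.ndarray,
    Z: np.ndarray,
    max_cn: int = 6,
    ploidy_candidates=DEFAULT_PLOIDY_GRID,
    w_baf: float = 1.0,
    state_weights: np.ndarray | None = None,
) -> IntegerCN:
    """Best integer (A, B) per state, jointly selecting the ploidy scale.

    ``state_weights`` (default: state occupancy in ``Z``) weight each
    state's fit error in the ploidy-scale selection.  Ties in the per-state
    argmin break toward the lexicographically smallest (a, b).
    """
    if max_cn < 1:
        raise ValueError("max_cn >= 1 required")
    mu_k, p_k = np.asarray(mu_k, float), np.asarray(p_k, float)
    if (mu_k <= 0).any() or ((p_k <= 0) | (p_k >= 1)).any():
        raise ValueError("require mu > 0 and 0 < p < 1")
    K = len(mu_k)
    if state_weights is None:
        state_weights = np.bincount(Z.ravel(), minlength=K).astype(float)
    pairs = _pairs(max_cn)
    totals = pairs.sum(axis=1)
    bafs = pairs[:, 1] / totals

    if np.allclose(mu_k, mu_k[0]) and np.allclose(p_k, p_k[0]) and K > 1:
        warnings.warn("all states identical; ploidy scale unidentifiable, using gamma = 2")
        ploidy_candidates = (2.0,)

    best = None
    for gamma in ploidy_candidates:
        err = (
            (totals[None, :] / gamma - mu_k[:, None]) ** 2
            + w_baf * (bafs[None, :] - p_k[:, None]) ** 2
        )  # (K, n_pairs)
        choice = np.argmin(err, axis=1)
        total_err = float((state_weights * err[np.arange(K), choice]).sum())
        if best is None or total_err < best[0]:
            best = (total_err, gamma, choice)
    _, gamma, choice = best
    sa, sb = pairs[choice, 0], pairs[choice, 1]
    return IntegerCN(A=sa[Z], B=sb[Z], ploidy_scale=float(gamma), state_A=sa, state_B=sb)


def classify_events(cn: IntegerCN, bins: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-bin per-clone event labels plus a cross-clone mirrored flag.

    Labels relative to a diploid (1, 1) baseline: ``neutral`` (1, 1);
    ``CNLOH`` one allele lost, total still 2; ``LOH`` one allele absent at
    other totals; ``del`` total < 2; ``amp`` total > 2.  A bin is
    ``mirrored`` when two clones carry opposite-haplotype imbalances
    (a > b in one, a < b in another).
    """
    G, M = cn.A.shape
    rows = []
    for j in range(G):
        orient = np.sign(cn.A[j] - cn.B[j])
        unbal = orient != 0
        mirrored = bool((orient[unbal] > 0).any() and (orient[unbal] < 0).any())
        for m in range(M):
            a, b = int(cn.A[j, m]), int(cn.B[j, m])
            t = a + b
            if (a, b) == (1, 1):
                label = "neutral"
            elif t == 2 and min(a, b) == 0:
                label = "CNLOH"
            elif min(a, b) == 0:
                label = "LOH"
            elif t < 2:
                label = "del"
            elif t > 2:
                label = "amp"
            else:
                label = "neutral"
            rows.append({"bin": j, "clone": m, "A": a, "B": b, "label": label,
                         "mirrored": mirrored})
    out = pd.DataFrame(rows)
    if bins is not None:
        out = out.merge(
            bins[["chrom", "start", "end"]].reset_index(names="bin"), on="bin", how="left"
        )
    return out
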