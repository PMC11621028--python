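"""Normal-spot identification, baseline expression, and ASE bin filtering.

Normal (non-tumor) spots carry a diploid, allelically balanced genome, so
their phased BAF sits at 0.5 genome-wide.  Clustering spots on per-bin BAF
and taking the cluster whose center is closest to 0.5 yields a normal set,
from which a baseline expression profile lambda (per-bin proportions) is
computed.  Bins whose pooled normal BAF deviates from 0.5 show allele-
specific expression unrelated to copy number and are masked from CNA
inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .phasing import BinnedGenome

__all__ = ["BaselineProfile", "identify_normal_spots", "compute_baseline", "filter_ase_bins"]


@dataclass
class BaselineProfile:
    normal_mask: np.ndarray  # per-spot bool
    lam: np.ndarray  # per-bin baseline expression proportion, sums to 1
    ase_mask: np.ndarray  # per-bin bool, True = retained


def identify_normal_spots(
    bg: BinnedGenome,
    n_clusters: int = 5,
    theta: np.ndarray | None = None,
    random_state: int = 0,
) -> np.ndarray:
    """Mark putative normal spots.

    With per-spot tumor proportions ``theta`` available, a spot is normal
    when theta < 0.5.  Otherwise spots are k-means clustered on per-bin
    phased BAF (missing bins imputed at 0.5) and the cluster whose mean
    |BAF - 0.5| is smallest is taken as normal.
    """
    if theta is not None:
        return np.asarray(theta) < 0.5
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    baf = bg.baf().T.copy()  # spot x bin
    baf[np.isnan(baf)] = 0.5
    n_clusters = min(n_clusters, bg.n_spots)
    km = KMeans(n_clusters=n_clusters, n_init=5, random_state=random_state).fit(baf)
    dev = np.abs(km.cluster_centers_ - 0.5).mean(axis=1)
    best = int(np.argmin(dev))
    mask = km.labels_ == best
    if mask.sum() <= 1:
        warnings.warn("normal cluster is degenerate (<= 1 spot)")
    return mask


def compute_baseline(bg: BinnedGenome, normal_mask: np.ndarray) -> np.ndarray:
    """Per-bin baseline expression proportions from pooled normal spots."""
    normal_mask = np.asarray(normal_mask, bool)
    if not normal_mask.any():
        raise ValueError("normal mask is empty")
    totals = bg.X[:, normal_mask].sum(axis=1).astype(float)
    s = totals.sum()
    if s == 0:
        raise ValueError("normal spots have zero expression")
    return totals / s


def filter_ase_bins(bg: BinnedGenome, normal_mask: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Mask bins with allele-specific expression in normal spots.

    Pooled normal (y, d) per bin is tested against BAF = 0.5 with an exact
    two-sided binomial test; Benjamini–Hochberg at ``alpha`` controls the
    FDR.  Bins with d = 0 carry no evidence and are retained.
    """
    normal_mask = np.asarray(normal_mask, bool)
    if not normal_mask.any():
        raise ValueError("normal mask is empty")
    y = bg.Y[:, normal_mask].sum(axis=1)
    d = bg.D[:, normal_mask].sum(axis=1)
    pvals = np.ones(bg.n_bins)
    for j in range(bg.n_bins):
        if d[j] > 0:
            pvals[j] = binomtest(int(y[j]), int(d[j]), 0.5).pvalue
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return ~reject
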