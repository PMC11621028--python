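"""LOH detection from BAF and per-spot tumor-proportion estimation.

In a region where the tumor lost one haplotype (LOH), a pure tumor spot
shows BAF 0 (or 1) while a pure normal spot shows 0.5.  For a spot that is
a mixture of tumor fraction theta and normal cells, with the lost allele
in the numerator and tumor RDR mu in the LOH region, the observed BAF is

    f = 0.5 (1 - theta) / (theta mu + (1 - theta)),

which inverts to  theta = (0.5 - f) / (0.5 + mu f - f).  LOH regions are
found by a genome-axis HMM over pooled bin BAFs under a single-clone
assumption; clusters whose BAF deviates from 0.5 by at least a threshold
(default 0.2) are called LOH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import betabinom

from . import hmm
from .phasing import BinnedGenome

__all__ = [
    "LOHRegions",
    "TumorProportions",
    "detect_loh",
    "estimate_theta",
    "forward_baf",
    "invert_baf",
]


@dataclass
class LOHRegions:
    bin_ids: np.ndarray  # indices into the BinnedGenome
    lost: np.ndarray  # per-bin lost haplotype, "B" (p < 0.5) or "A"
    baf: np.ndarray  # per-bin estimated cluster BAF
    mu: float = 1.0  # RDR of the LOH state (support-weighted across regions)

    def __len__(self):
        return len(self.bin_ids)


@dataclass
class TumorProportions:
    theta: np.ndarray  # per-spot tumor proportion in [0, 1]
    f: np.ndarray  # per-spot pooled LOH BAF
    support: np.ndarray  # per-spot total LOH allele UMIs
    imputed: np.ndarray = field(default=None)  # spots with support below minimum


def forward_baf(theta, mu):
    """Expected LOH-region BAF of a tumor/normal mixture (lost allele in numerator)."""
    theta = np.asarray(theta, float)
    return 0.5 * (1 - theta) / (theta * mu + (1 - theta))


def invert_baf(f, mu):
    """Tumor proportion from observed LOH BAF; exact inverse of :func:`forward_baf`."""
    f = np.asarray(f, float)
    return (0.5 - f) / (0.5 + mu * f - f)


def _fit_baf_hmm(y, d, chains, K=5, max_iter=30, tol=1e-6):
    """Small Baum–Welch for beta-binomial BAF states along the genome."""
    p = np.linspace(0.1, 0.9, K)
    tau, t = 30.0, 1 - 1e-3

    def emis(p, tau):
        return np.stack(
            [betabinom.logpmf(y, d, tau * pi, tau * (1 - pi)) for pi in p], axis=1
        )

    prev = -np.inf
    for _ in range(max_iter):
        E = emis(p, tau)
        lt = np.log(np.full((K, K), (1 - t) / max(K - 1, 1)) + np.eye(K) * (t - (1 - t) / max(K - 1, 1)))
        ls = np.full(K, -np.log(K))
        ll, gamma, xi = 0.0, np.zeros((len(y), K)), np.zeros((K, K))
        for ch in chains:
            ll_c, g, x = hmm.forward_backward(E[ch], lt, ls)
            ll, gamma[ch] = ll + ll_c, g
            xi += x
        if ll - prev < tol * max(1.0, abs(ll)) and ll >= prev:
            break
        prev = ll
        if xi.sum() > 0 and K > 1:
            t = float(np.clip(np.trace(xi) / xi.sum(), 1e-6, 1 - 1e-6))
        for i in range(K):
            def q(pi):
                return gamma[:, i] @ betabinom.logpmf(y, d, tau * pi, tau * (1 - pi))
            res = minimize_scalar(lambda v: -q(v), bounds=(1e-3, 1 - 1e-3), method="bounded")
            if -res.fun > q(p[i]):
                p[i] = res.x
        def qt(tv):
            return float((gamma * emis(p, tv)).sum())
        res = minimize_scalar(lambda v: -qt(np.exp(v)), bounds=(0.0, np.log(5e3)), method="bounded")
        if -res.fun > qt(tau):
            tau = float(np.exp(res.x))

    E = emis(p, tau)
    lt = np.log(np.full((K, K), (1 - t) / max(K - 1, 1)) + np.eye(K) * (t - (1 - t) / max(K - 1, 1)))
    ls = np.full(K, -np.log(K))
    path = np.empty(len(y), dtype=int)
    for ch in chains:
        path[ch] = hmm.viterbi(E[ch], lt, ls)
    return p, path


def detect_loh(
    bg: BinnedGenome,
    threshold: float = 0.2,
    lam: np.ndarray | None = None,
    n_states: int = 5,
) -> LOHRegions:
    """Flag genomic bins in LOH from pooled BAF under a single-clone HMM.

    ``threshold`` (default 0.2) is the minimum deviation of the estimated
    cluster BAF from 0.5.  When a baseline profile ``lam`` is given, the
    LOH state's RDR mu is estimated as the observed/expected expression
    ratio over the flagged bins; otherwise mu defaults to 1.
    """
    if not 0 < threshold < 0.5:
        raise ValueError("threshold must lie in (0, 0.5)")
    y = bg.Y.sum(axis=1).astype(float)
    d = bg.D.sum(axis=1).astype(float)
    p, path = _fit_baf_hmm(y, d, bg.chain_slices(), K=n_states)
    state_baf = p[path]
    is_loh = np.abs(state_baf - 0.5) >= threshold
    ids = np.where(is_loh)[0]
    mu = 1.0
    if lam is not None and len(ids):
        x_tot = bg.X.sum(axis=1).astype(float)
        lam_frac = lam[ids].sum()
        if lam_frac > 0 and x_tot.sum() > 0:
            obs = x_tot[ids].sum() / x_tot.sum()
            mu = float(obs / lam_frac)
    return LOHRegions(
        bin_ids=ids,
        lost=np.where(state_baf[ids] < 0.5, "B", "A"),
        baf=state_baf[ids],
        mu=mu,
    )


def estimate_theta(
    bg: BinnedGenome,
    loh: LOHRegions,
    mu: float | None = None,
    min_support: int = 10,
    k_impute: int = 6,
) -> TumorProportions:
    """Per-spot tumor proportion from pooled allele counts over LOH bins.

    Counts are oriented so the lost haplotype is in the numerator, pooled
    over all LOH bins per spot, and inverted through the mixture formula.
    Spots with fewer than ``min_support`` LOH UMIs get theta imputed from
    the mean of their ``k_impute`` nearest spatial neighbors.
    """
    if len(loh) == 0:
        raise ValueError("no LOH regions; tumor proportion unavailable")
    mu = loh.mu if mu is None else mu
    Y = bg.Y[loh.bin_ids].astype(float)
    D = bg.D[loh.bin_ids].astype(float)
    lost_num = np.where((loh.lost == "B")[:, None], Y, D - Y)
    num = lost_num.sum(axis=0)
    support = D.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(support > 0, num / np.maximum(support, 1), np.nan)
    theta = np.clip(invert_baf(np.nan_to_num(f, nan=0.5), mu), 0.0, 1.0)

    low = support < min_support
    if low.any() and (~low).any():
        from scipy.spatial import cKDTree

        tree = cKDTree(bg.S[~low])
        k = min(k_impute, (~low).sum())
        _, nn = tree.query(bg.S[low], k=k)
        nn = np.atleast_2d(nn)
        theta[low] = theta[~low][nn].mean(axis=1)
    return TumorProportions(theta=theta, f=f, support=support, imputed=low)
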