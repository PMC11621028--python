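"""Pseudobulk phase-error correction and haplotype-aware genomic binning.

Population-based phasing is accurate for nearby SNPs but accumulates
switch errors over distance.  Because every cell in a sample carries the
same parental haplotypes, pooling allele counts over all spots yields a
pseudobulk B-allele-frequency (BAF) track in which large imbalanced
copy-number segments appear as contiguous blocks of BAF != 0.5.  An HMM
over joint hidden states (phase label h_g, BAF cluster z_g) re-phases each
SNP: emissions are beta-binomial with the cluster BAF p_i in one phase
orientation and 1 - p_i in the other, and transitions factorize into a
BAF-state chain (self-transition t) and a phase chain (self-transition q).

After phasing, the genome is partitioned into variable-length bins, each
accumulating pooled allele counts until a minimum total is reached, and
per-spot counts are aggregated per bin with the inferred orientation.  The
inferred haplotype 1 is called the B haplotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import betabinom

from . import hmm
from .io import RawBundle, _chrom_key

__all__ = [
    "PseudobulkAlleles",
    "PhasingModel",
    "PhaseAssignment",
    "BinnedGenome",
    "pseudobulk",
    "phasing_emission_loglik",
    "fit_phasing_hmm",
    "make_bins",
    "aggregate",
]

HAP1, HAP2 = 0, 1  # phase labels; HAP1 is the inferred B haplotype


@dataclass
class PseudobulkAlleles:
    y0: np.ndarray  # per-SNP haplotype-1 counts summed over spots
    d0: np.ndarray  # per-SNP total counts summed over spots
    chrom: np.ndarray  # per-SNP chromosome label

    def __post_init__(self):
        if (self.y0 > self.d0).any():
            raise ValueError("y0 > d0")


@dataclass
class PhasingModel:
    p: np.ndarray  # per-cluster BAF, ascending, in (0, 0.5]
    tau: float  # beta-binomial concentration
    t: float  # BAF-cluster self-transition
    q: float  # phase self-transition
    loglik_trace: list = field(default_factory=list)
    converged: bool = True

    @property
    def n_states(self) -> int:
        return 2 * len(self.p)

    def joint_log_trans(self) -> np.ndarray:
        K = len(self.p)
        tz = np.full((K, K), (1 - self.t) / max(K - 1, 1))
        np.fill_diagonal(tz, self.t if K > 1 else 1.0)
        th = np.array([[self.q, 1 - self.q], [1 - self.q, self.q]])
        return np.log(np.kron(tz, th))

    def joint_log_start(self) -> np.ndarray:
        return np.full(self.n_states, -np.log(self.n_states))


@dataclass
class PhaseAssignment:
    h: np.ndarray  # per-SNP phase in {HAP1, HAP2}
    z: np.ndarray  # per-SNP BAF-cluster index
    posterior_h1: np.ndarray  # P(h_g = haplotype 1 | data)


@dataclass
class BinnedGenome:
    """Per-bin phased counts plus spot geometry carried through the pipeline."""

    bins: pd.DataFrame  # chrom, start, end, n_snps, n_genes
    X: np.ndarray  # bin x spot transcripts
    Y: np.ndarray  # bin x spot B-haplotype counts
    D: np.ndarray  # bin x spot total allele counts
    S: np.ndarray
    slice_id: np.ndarray
    barcodes: np.ndarray

    def __post_init__(self):
        if (self.Y > self.D).any():
            raise ValueError("Y > D")

    @property
    def n_bins(self) -> int:
        return self.X.shape[0]

    @property
    def n_spots(self) -> int:
        return self.X.shape[1]

    def chain_slices(self) -> list[slice]:
        """Contiguous bin ranges per chromosome (HMM chain boundaries)."""
        chrom = self.bins["chrom"].to_numpy()
        out, start = [], 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                out.append(slice(start, i))
                start = i
        return out

    def baf(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.D > 0, self.Y / np.maximum(self.D, 1), np.nan)


def pseudobulk(bundle: RawBundle) -> PseudobulkAlleles:
    """Pool allele counts over all spots (all cells share the same haplotypes)."""
    return PseudobulkAlleles(
        y0=bundle.Y0.sum(axis=1),
        d0=bundle.D0.sum(axis=1),
        chrom=bundle.snp_index["chrom"].to_numpy(),
    )


def phasing_emission_loglik(y, d, h, p_i: float, tau: float):
    """Log beta-binomial emission for one SNP under phase ``h`` and cluster BAF ``p_i``."""
    if not 0 < p_i < 1 or tau <= 0:
        raise ValueError("require 0 < p_i < 1 and tau > 0")
    y, d = np.asarray(y), np.asarray(d)
    if (y < 0).any() or (y > d).any():
        raise ValueError("require 0 <= y <= d")
    a, b = (tau * p_i, tau * (1 - p_i)) if h == HAP1 else (tau * (1 - p_i), tau * p_i)
    return betabinom.logpmf(y, d, a, b)


def _emission_matrix(y, d, p, tau) -> np.ndarray:
    """(G, 2K) log emissions; joint state index = cluster * 2 + phase."""
    G, K = len(y), len(p)
    E = np.empty((G, 2 * K))
    for i, pi in enumerate(p):
        E[:, 2 * i + HAP1] = betabinom.logpmf(y, d, tau * pi, tau * (1 - pi))
        E[:, 2 * i + HAP2] = betabinom.logpmf(y, d, tau * (1 - pi), tau * pi)
    return E


def _chain_bounds(chrom: np.ndarray) -> list[slice]:
    out, start = [], 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            out.append(slice(start, i))
            start = i
    return out


def fit_phasing_hmm(
    pb: PseudobulkAlleles,
    K_phase: int = 5,
    init: PhasingModel | None = None,
    max_iter: int = 30,
    tol: float = 1e-6,
) -> tuple[PhasingModel, PhaseAssignment]:
    """Baum–Welch fit of the joint (phase, BAF-cluster) HMM on pseudobulk counts.

    Chromosomes are independent chains (the Markov chain restarts at each
    chromosome with the start distribution).  The M-step maximizes the
    expected complete-data log-likelihood coordinate-wise: closed form for
    the transition parameters t and q, bounded scalar optimization for each
    cluster BAF p_i and the shared concentration tau — a generalized EM, so
    the observed-data log-likelihood is non-decreasing.  The returned phase
    assignment is the joint MAP (Viterbi) path.
    """
    y, d = pb.y0.astype(float), pb.d0.astype(float)
    if init is None:
        p0 = np.linspace(0.5 / K_phase, 0.5, K_phase) if K_phase > 1 else np.array([0.5])
        model = PhasingModel(p=p0, tau=30.0, t=1 - 1e-4, q=1 - 1e-3)
    else:
        model = init
    chains = _chain_bounds(pb.chrom)
    K = len(model.p)
    prev_ll = -np.inf
    model.converged = False
    for _ in range(max_iter):
        E = _emission_matrix(y, d, model.p, model.tau)
        lt, ls = model.joint_log_trans(), model.joint_log_start()
        ll = 0.0
        gamma = np.zeros((len(y), 2 * K))
        xi = np.zeros((2 * K, 2 * K))
        for ch in chains:
            ll_c, g, x = hmm.forward_backward(E[ch], lt, ls)
            ll += ll_c
            gamma[ch] = g
            xi += x
        model.loglik_trace.append(ll)
        if ll - prev_ll < tol * max(1.0, abs(ll)) and ll >= prev_ll:
            model.converged = True
            break
        prev_ll = ll

        # M-step: transitions (closed form). Joint index = cluster*2 + phase.
        cl = np.repeat(np.arange(K), 2)
        ph = np.tile(np.arange(2), K)
        same_z = xi[cl[:, None] == cl[None, :]].sum()
        same_h = xi[ph[:, None] == ph[None, :]].sum()
        tot = xi.sum()
        if tot > 0 and K > 1:
            model.t = float(np.clip(same_z / tot, 1e-6, 1 - 1e-6))
        if tot > 0:
            model.q = float(np.clip(same_h / tot, 1e-6, 1 - 1e-6))

        # M-step: cluster BAFs (bounded 1-D maximization of Q each).
        def q_p(pi, i):
            e1 = betabinom.logpmf(y, d, model.tau * pi, model.tau * (1 - pi))
            e2 = betabinom.logpmf(y, d, model.tau * (1 - pi), model.tau * pi)
            return gamma[:, 2 * i + HAP1] @ e1 + gamma[:, 2 * i + HAP2] @ e2

        for i in range(K):
            res = minimize_scalar(
                lambda v: -q_p(v, i), bounds=(1e-3, 0.5), method="bounded",
                options={"xatol": 1e-5},
            )
            if -res.fun > q_p(model.p[i], i):
                model.p[i] = res.x

        def q_tau(tau):
            E2 = _emission_matrix(y, d, model.p, tau)
            return float((gamma * E2).sum())

        res = minimize_scalar(
            lambda v: -q_tau(np.exp(v)), bounds=(np.log(1.0), np.log(5e3)),
            method="bounded", options={"xatol": 1e-3},
        )
        if -res.fun > q_tau(model.tau):
            model.tau = float(np.exp(res.x))
    else:
        warnings.warn("phasing HMM did not converge; returning best iterate")

    E = _emission_matrix(y, d, model.p, model.tau)
    lt, ls = model.joint_log_trans(), model.joint_log_start()
    path = np.empty(len(y), dtype=int)
    gamma = np.zeros((len(y), 2 * K))
    for ch in chains:
        path[ch] = hmm.viterbi(E[ch], lt, ls)
        _, g, _ = hmm.forward_backward(E[ch], lt, ls)
        gamma[ch] = g
    assignment = PhaseAssignment(
        h=path % 2, z=path // 2, posterior_h1=gamma[:, HAP1::2].sum(axis=1)
    )
    return model, assignment


def make_bins(snp_index: pd.DataFrame, pb: PseudobulkAlleles, min_total: int = 300) -> list[dict]:
    """Greedy variable-length binning of SNPs along each chromosome.

    SNPs are accumulated left to right until the pooled total allele count
    reaches ``min_total``; the trailing remainder of each chromosome forms
    a final, possibly deficient, bin.
    """
    if min_total <= 0:
        raise ValueError("min_total must be positive")
    bins = []
    for ch in _chain_bounds(pb.chrom):
        idx = np.arange(ch.start, ch.stop)
        acc, members = 0, []
        for g in idx:
            members.append(g)
            acc += pb.d0[g]
            if acc >= min_total:
                bins.append({"chrom": pb.chrom[g], "snps": members})
                acc, members = 0, []
        if members:
            bins.append({"chrom": pb.chrom[members[-1]], "snps": members})
    for b in bins:
        pos = snp_index["pos"].to_numpy()[b["snps"]]
        b["start"], b["end"] = int(pos.min()), int(pos.max())
    return bins


def aggregate(bundle: RawBundle, pa: PhaseAssignment, bins: list[dict]) -> BinnedGenome:
    """Haplotype-aware aggregation of per-spot counts into genomic bins.

    For a SNP phased to haplotype 1 its haplotype-1 count contributes to
    the bin's B count Y; for haplotype 2 the complement D0 - Y0 does.
    Gene transcript counts are assigned to the bin containing (or nearest
    to, on the same chromosome) the gene's transcription start.
    """
    n_bins, n_spots = len(bins), bundle.n_spots
    X = np.zeros((n_bins, n_spots), dtype=np.int64)
    Y = np.zeros((n_bins, n_spots), dtype=np.int64)
    D = np.zeros((n_bins, n_spots), dtype=np.int64)
    for j, b in enumerate(bins):
        gs = np.asarray(b["snps"])
        D[j] = bundle.D0[gs].sum(axis=0)
        flip = pa.h[gs] == HAP2
        Y[j] = np.where(flip[:, None], bundle.D0[gs] - bundle.Y0[gs], bundle.Y0[gs]).sum(axis=0)

    # gene -> bin by transcription start (nearest bin interval on the chromosome)
    n_genes_per_bin = np.zeros(n_bins, dtype=int)
    by_chrom: dict[str, list[int]] = {}
    for j, b in enumerate(bins):
        by_chrom.setdefault(str(b["chrom"]), []).append(j)
    for gi, row in bundle.gene_index.iterrows():
        cand = by_chrom.get(str(row["chrom"]))
        if not cand:
            continue
        tss = row["start"]
        dist = [
            0 if bins[j]["start"] <= tss <= bins[j]["end"]
            else min(abs(tss - bins[j]["start"]), abs(tss - bins[j]["end"]))
            for j in cand
        ]
        j = cand[int(np.argmin(dist))]
        X[j] += bundle.X0[gi]
        n_genes_per_bin[j] += 1

    meta = pd.DataFrame(
        {
            "chrom": [b["chrom"] for b in bins],
            "start": [b["start"] for b in bins],
            "end": [b["end"] for b in bins],
            "n_snps": [len(b["snps"]) for b in bins],
            "n_genes": n_genes_per_bin,
            "snp_ids": [list(b["snps"]) for b in bins],
        }
    )
    order = np.lexsort((meta["start"], meta["chrom"].map(_chrom_key)))
    return BinnedGenome(
        bins=meta.iloc[order].reset_index(drop=True),
        X=X[order],
        Y=Y[order],
        D=D[order],
        S=bundle.S,
        slice_id=bundle.slice_id,
        barcodes=bundle.barcodes,
    )
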