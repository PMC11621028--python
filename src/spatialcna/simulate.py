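"""Synthetic Visium-like data with planted clones, CNAs and ground truth.

The generator emulates the measurement model the inference assumes:
spots sit on a hexagonal lattice (one or more slices with z offsets),
clone territories are Voronoi cells of random seeds, each clone carries an
allele-specific integer copy-number profile over genomic bins, and each
spot mixes tumor and normal signal according to a tumor proportion field.
Transcripts are negative binomial around the baseline scaled by the
total-copy RDR; phased allele counts are beta-binomial around the mixed
BAF; population phasing is corrupted by first-order Markov (block) switch
errors.  Everything is deterministic given the seed, and the planted
labels, proportions, copies, phases and generating tree are returned as
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import RawBundle

__all__ = ["SimConfig", "GroundTruth", "simulate", "simulate_tree_profiles", "mirrored_profiles"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults target a mid-size Visium section: ~500 spots at 50 UMIs-scale
    depth per axis of interest, ~100 bins with 8 SNPs and 5 genes each
    (the per-bin occupancy real runs produce), moderate overdispersion,
    and a 2% switch-error rate typical of population phasing over long
    ranges.
    """

    nx: int = 23
    ny: int = 22
    n_slices: int = 1
    z_step: float = 100.0  # inter-slice spacing, same units as the lattice pitch
    pitch: float = 1.0  # lattice spacing (one unit ~ one spot diameter)
    M: int = 3
    n_bins: int = 100
    n_chrom: int = 4
    snps_per_bin: int = 8
    genes_per_bin: int = 5
    umi_per_spot: int = 3000
    allele_umi_per_spot: int = 300
    theta: float | np.ndarray = 1.0  # tumor proportion (scalar or per-spot)
    normal_fraction: float = 0.0  # fraction of spots that are pure normal
    switch_rate: float = 0.02
    nb_phi: float = 0.05  # negative-binomial dispersion
    bb_tau: float = 60.0  # beta-binomial concentration
    ploidy: float = 2.0
    clone_profiles: np.ndarray | None = None  # (n_bins, M, 2) integer (A, B)
    seed: int = 0


@dataclass
class GroundTruth:
    labels: np.ndarray  # per-spot clone (-1 = pure normal spot)
    theta: np.ndarray  # per-spot tumor proportion
    A: np.ndarray  # bin x clone
    B: np.ndarray
    h_flip: np.ndarray  # per-SNP switch-error indicator (1 = flipped)
    lam: np.ndarray  # per-bin true baseline expression proportions
    snp_bin: np.ndarray  # per-SNP bin index
    gene_bin: np.ndarray  # per-gene bin index
    loh_bins: np.ndarray  # bins with a haplotype fully lost in some clone
    tree: nx.DiGraph | None = None


def _hex_lattice(nx_, ny_, pitch):
    xs, ys = [], []
    for r in range(ny_):
        for c in range(nx_):
            xs.append(pitch * (c + 0.5 * (r % 2)))
            ys.append(pitch * r * np.sqrt(3) / 2)
    return np.column_stack([xs, ys])


def mirrored_profiles(n_bins: int, M: int = 3) -> np.ndarray:
    """A standard 3-clone test genome exercising the detectable event types.

    Segments (fractions of the genome): a truncal deletion (1, 0) shared by
    all clones; a mirrored pair — clone 1 (2, 1) vs clone 2 (1, 2); a CNLOH
    (2, 0) in clone 2; a private (2, 1) amplification and a private (0, 1)
    mirrored LOH in clone 3 (if present); remaining bins diploid (1, 1).
    The distinct non-diploid states fit in three mirrored pairs, matching
    the default state-space capacity.
    """
    prof = np.ones((n_bins, M, 2), dtype=int)
    q = n_bins // 10
    prof[0 * q : 2 * q, :, :] = (1, 0)  # truncal LOH, B lost
    prof[2 * q : 4 * q, 0, :] = (2, 1)  # mirrored ...
    prof[2 * q : 4 * q, 1, :] = (1, 2)  # ... pair
    prof[4 * q : 6 * q, 1, :] = (2, 0)  # CNLOH in clone 2
    if M > 2:
        prof[6 * q : 8 * q, 2, :] = (2, 1)  # private amplification in clone 3
        prof[8 * q : 9 * q, 2, :] = (0, 1)  # private LOH, A lost
    return prof


def simulate_tree_profiles(
    M: int, n_loh: int, seed: int = 0, n_bins: int = 60, seg_bins: int = 4
):
    """Clone profiles generated by dropping LOH markers along a random tree.

    A random rooted binary tree over the M clones is drawn; each of the
    ``n_loh`` markers is a disjoint ``seg_bins``-bin segment losing one
    haplotype on one random edge, inherited by all descendant clones
    (irreversibility holds by construction).  Requires n_loh >= M - 1 so
    every clone can be distinguished.
    """
    if n_loh < M - 1:
        raise ValueError("need at least M - 1 markers")
    if n_loh * seg_bins > n_bins:
        raise ValueError("genome too small for the requested markers")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_node("root", clone=None)
    if M == 1:
        g.add_node("c0", clone=0)
        g.add_edge("root", "c0")
        profiles = np.ones((n_bins, 1, 2), dtype=int)
        return profiles, g

    # random topology by sequential attachment
    nodes = ["c0", "c1"]
    g.add_node("v0", clone=None)
    g.add_edge("root", "v0")
    g.add_node("c0", clone=0)
    g.add_node("c1", clone=1)
    g.add_edge("v0", "c0")
    g.add_edge("v0", "c1")
    for m in range(2, M):
        # split a random pendant-or-internal edge with a new internal node
        edges = [e for e in g.edges if e[0] != "root" or True]
        u, v = edges[rng.integers(len(edges))]
        new = f"v{m - 1}"
        g.remove_edge(u, v)
        g.add_node(new, clone=None)
        g.add_edge(u, new)
        g.add_edge(new, v)
        leaf = f"c{m}"
        g.add_node(leaf, clone=m)
        g.add_edge(new, leaf)

    below = {}
    for n in nx.dfs_postorder_nodes(g, "root"):
        kids = list(g.successors(n))
        if not kids:
            below[n] = {g.nodes[n]["clone"]}
        else:
            below[n] = set().union(*(below[k] for k in kids))

    profiles = np.ones((n_bins, M, 2), dtype=int)
    edges = [e for e in g.edges]
    # ensure each non-root edge gets at least one marker when possible
    order = list(rng.permutation(len(edges)))
    assignments = [edges[order[i % len(edges)]] for i in range(n_loh)]
    for e in g.edges:
        g.edges[e]["markers"] = []
    for c, (u, v) in enumerate(assignments):
        seg = slice(c * seg_bins, (c + 1) * seg_bins)
        hap = int(rng.integers(2))  # 0 = lose B, 1 = lose A
        for m in below[v]:
            profiles[seg, m, 1 - hap] = 0
        g.edges[u, v]["markers"].append(c)
    return profiles, g


def simulate(config: SimConfig) -> tuple[RawBundle, GroundTruth]:
    """Draw one dataset and its ground truth (bit-reproducible given seed)."""
    rng = np.random.default_rng(config.seed)
    S_one = _hex_lattice(config.nx, config.ny, config.pitch)
    n_per = len(S_one)
    S = np.vstack([S_one] * config.n_slices)
    slice_id = np.repeat([f"s{i}" for i in range(config.n_slices)], n_per)
    N = len(S)

    prof = (
        config.clone_profiles
        if config.clone_profiles is not None
        else mirrored_profiles(config.n_bins, config.M)
    )
    G_bins, M = prof.shape[0], prof.shape[1]
    A, B = prof[:, :, 0], prof[:, :, 1]

    # clone territories: Voronoi cells of random seeds, shared across slices
    seeds = S_one[rng.choice(n_per, size=M, replace=False)]
    d2 = ((S[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)

    theta = np.full(N, config.theta, float) if np.isscalar(config.theta) else np.asarray(
        config.theta, float
    ).copy()
    if config.normal_fraction > 0:
        normal_spots = rng.random(N) < config.normal_fraction
        theta[normal_spots] = 0.0
        labels = np.where(normal_spots, -1, labels)

    # genome layout
    snp_bin = np.repeat(np.arange(G_bins), config.snps_per_bin)
    gene_bin = np.repeat(np.arange(G_bins), config.genes_per_bin)
    n_snps, n_genes = len(snp_bin), len(gene_bin)
    bins_per_chrom = int(np.ceil(G_bins / config.n_chrom))
    bin_chrom = np.array([f"chr{1 + j // bins_per_chrom}" for j in range(G_bins)])
    bin_width = 1_000_000
    snp_pos = np.empty(n_snps, dtype=int)
    gene_start = np.empty(n_genes, dtype=int)
    for j in range(G_bins):
        local = (j % bins_per_chrom) * bin_width
        sl = snp_bin == j
        snp_pos[sl] = local + np.arange(sl.sum()) * (bin_width // (config.snps_per_bin + 1)) + 1000
        gl = gene_bin == j
        gene_start[gl] = local + np.arange(gl.sum()) * (bin_width // (config.genes_per_bin + 1)) + 500

    # baseline expression: per-gene weights, bin lambda = member sum
    gene_w = rng.dirichlet(np.full(n_genes, 5.0))
    lam = np.array([gene_w[gene_bin == j].sum() for j in range(G_bins)])

    # per-spot effective RDR / BAF per bin
    total_cn = np.maximum(A + B, 1)
    mu = total_cn / config.ploidy  # (G, M)
    with np.errstate(invalid="ignore"):
        p_state = B / np.maximum(A + B, 1)
    clone_mu = np.where(labels[None, :] >= 0, mu[:, np.clip(labels, 0, None)], 1.0)
    clone_p = np.where(labels[None, :] >= 0, p_state[:, np.clip(labels, 0, None)], 0.5)
    th = theta[None, :]
    rdr_eff = th * clone_mu + (1 - th)  # (G, N)
    baf_eff = (th * clone_p * clone_mu + 0.5 * (1 - th)) / rdr_eff

    # transcripts: NB per gene
    gene_rate = gene_w[:, None] * rdr_eff[gene_bin]  # (n_genes, N)
    gene_rate = gene_rate / gene_rate.sum(axis=0, keepdims=True)
    mean_x = config.umi_per_spot * gene_rate
    r = 1.0 / config.nb_phi
    X0 = rng.negative_binomial(r, r / (r + np.maximum(mean_x, 1e-9)))

    # alleles: total depth Poisson, B-count beta-binomial around mixed BAF
    snp_w = rng.dirichlet(np.full(n_snps, 10.0))
    snp_rate = snp_w[:, None] * rdr_eff[snp_bin]
    snp_rate = snp_rate / snp_rate.sum(axis=0, keepdims=True)
    D0 = rng.poisson(config.allele_umi_per_spot * snp_rate)
    baf_snp = np.clip(baf_eff[snp_bin], 1e-4, 1 - 1e-4)
    alpha = config.bb_tau * baf_snp
    beta_par = config.bb_tau - alpha
    pdraw = rng.beta(alpha, beta_par)
    yB = rng.binomial(D0, pdraw)

    # population-phasing switch errors: first-order Markov flip process
    flip = np.zeros(n_snps, dtype=int)
    state = 0
    prev_chrom = None
    for g in range(n_snps):
        ch = bin_chrom[snp_bin[g]]
        if ch != prev_chrom:
            state = 0  # phasing restarts per chromosome
            prev_chrom = ch
        if rng.random() < config.switch_rate:
            state = 1 - state
        flip[g] = state
    Y0 = np.where(flip[:, None] == 1, D0 - yB, yB)

    snp_index = pd.DataFrame(
        {"chrom": bin_chrom[snp_bin], "pos": snp_pos, "phase_flag": 0}
    )
    gene_index = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(n_genes)],
            "chrom": bin_chrom[gene_bin],
            "start": gene_start,
            "end": gene_start + 2000,
            "ig": False,
            "hla": False,
        }
    )
    bundle = RawBundle(
        X0=X0.astype(np.int64),
        Y0=Y0.astype(np.int64),
        D0=D0.astype(np.int64),
        S=S,
        slice_id=slice_id,
        barcodes=np.array([f"spot{i}" for i in range(N)]),
        snp_index=snp_index,
        gene_index=gene_index,
    )
    gt = GroundTruth(
        labels=labels,
        theta=theta,
        A=A,
        B=B,
        h_flip=flip,
        lam=lam,
        snp_bin=snp_bin,
        gene_bin=gene_bin,
        loh_bins=np.where((np.minimum(A, B) == 0).any(axis=1))[0],
    )
    return bundle, gt
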