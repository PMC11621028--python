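"""Joint inference of cancer clones and allele-specific copy-number states.

Each genomic bin in each clone carries one of K latent copy-number states;
a state k has a latent read-depth ratio (RDR) mu_k — expression relative
to the diploid baseline — and a latent B-allele frequency (BAF) p_k.
Transcript counts follow a negative binomial whose mean is the spot total
scaled by the baseline proportion lambda_j and the state RDR; allele
counts follow a beta-binomial with mean p_k.  When a per-spot tumor
proportion theta is supplied, the state parameters are mixed with the
normal (diploid, balanced) state:

    RDR_eff = theta mu_k + (1 - theta)
    BAF_eff = (theta p_k mu_k + 0.5 (1 - theta)) / (theta mu_k + (1 - theta))

Copy-number states are correlated along the genome by a Markov chain;
clone labels are correlated in space by a Potts-type Markov random field
over a spot neighbor graph.  Inference is block coordinate ascent on the
joint objective

    J = sum_s sum_j log f(x_sj, y_sj | Z_{j, l_s}) + log P(Z) + beta * Potts(l),

alternating exact Viterbi updates of Z per clone, iterated-conditional-
modes updates of l, and safeguarded parameter updates (each update is kept
only if it does not decrease J), so J is non-decreasing by construction.
The per-spot expression normalizer C_s (which makes state means sum to
the observed spot total) is itself a model field updated under the same
safeguard, keeping every other step an exact maximization.

Imbalanced states come in mirrored pairs sharing mu with BAFs p and 1 - p,
so the same imbalance can be carried on either haplotype — this is what
makes mirrored subclonal CNAs (opposite haplotypes altered in different
clones) detectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import betabinom, nbinom

from . import hmm
from .phasing import BinnedGenome

__all__ = [
    "NeighborGraph",
    "CloneModel",
    "build_graph",
    "emission_loglik",
    "hmm_update",
    "hmrf_update",
    "fit",
    "merge_clones",
]

_MU_BOUNDS = (0.05, 8.0)
_P_EPS = 1e-3


# ------------------------------------------------------------------ graph


@dataclass
class NeighborGraph:
    """Symmetric weighted spot adjacency (spatial kNN + optional inter-slice
    alignment edges + optional expression-similarity edges)."""

    n_spots: int
    neighbors: list[np.ndarray]  # per spot, neighbor indices
    weights: list[np.ndarray]  # per spot, matching edge weights

    def degree(self, s: int) -> int:
        return len(self.neighbors[s])

    @classmethod
    def from_edges(cls, n_spots: int, edges: dict[tuple[int, int], float]):
        nb = [[] for _ in range(n_spots)]
        wt = [[] for _ in range(n_spots)]
        for (i, j), w in sorted(edges.items()):
            nb[i].append(j)
            wt[i].append(w)
            nb[j].append(i)
            wt[j].append(w)
        return cls(
            n_spots,
            [np.asarray(a, int) for a in nb],
            [np.asarray(a, float) for a in wt],
        )


def build_graph(
    S: np.ndarray,
    slice_id: np.ndarray,
    W: dict | None = None,
    k_spatial: int = 6,
    expr_weight: float = 0.0,
    expr_features: np.ndarray | None = None,
) -> NeighborGraph:
    """Spot neighbor graph: per-slice spatial kNN, plus inter-slice edges
    where the alignment matrix ``W`` carries appreciable mass (entries above
    half the mean positive entry), plus expression-kNN edges scaled by
    ``expr_weight`` when requested.

    ``W`` maps ``(slice_a, slice_b)`` to a matrix indexed by the spots of
    the two slices in their within-slice order.
    """
    from sklearn.neighbors import NearestNeighbors

    S = np.asarray(S, float)
    n = len(S)
    edges: dict[tuple[int, int], float] = {}

    slice_spots = {lab: np.where(slice_id == lab)[0] for lab in np.unique(slice_id)}
    for spots in slice_spots.values():
        if len(spots) < 2:
            continue
        k = min(k_spatial, len(spots) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(S[spots])
        _, idx = nn.kneighbors(S[spots])
        for a, row in zip(spots, spots[idx[:, 1:]]):
            for b in row:
                edges[(min(a, b), max(a, b))] = 1.0

    if W:
        for (sa, sb), mat in W.items():
            ia, ib = slice_spots[sa], slice_spots[sb]
            mat = np.asarray(mat, float)
            if mat.shape != (len(ia), len(ib)):
                raise ValueError(f"alignment matrix for ({sa},{sb}) has wrong shape")
            pos = mat[mat > 0]
            if pos.size == 0:
                continue
            thr = 0.5 * pos.mean()
            for r, c in zip(*np.where(mat > thr)):
                a, b = ia[r], ib[c]
                key = (min(a, b), max(a, b))
                edges[key] = max(edges.get(key, 0.0), 1.0)

    if expr_weight > 0 and expr_features is not None:
        k = min(k_spatial, n - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(expr_features)
        _, idx = nn.kneighbors(expr_features)
        for a in range(n):
            for b in idx[a, 1:]:
                key = (min(a, int(b)), max(a, int(b)))
                edges[key] = edges.get(key, 0.0) + expr_weight

    return NeighborGraph.from_edges(n, edges)


# ----------------------------------------------------------------- states


def make_states(n_states: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Initial tied state layout.

    ``n_states`` must be odd: B = (n_states - 1) / 2 mirrored imbalanced
    pairs (state 2b has BAF p_b < 0.5, state 2b+1 its mirror 1 - p_b, both
    sharing mu_b) plus one balanced diploid anchor state (mu = 1, p = 0.5)
    at the end.  ``n_states = 1`` is the degenerate single-state model
    (free p, mu = 1).
    """
    if n_states == 1:
        return np.array([1.0]), np.array([0.45]), 0
    if n_states % 2 == 0:
        raise ValueError("n_states must be odd (mirrored pairs + balanced state)")
    B = (n_states - 1) // 2
    mus = np.concatenate([np.linspace(0.5, 2.0, B), [1.0]])
    ps = np.linspace(0.1, 0.4, B)
    return mus, ps, B


def expand_states(mus: np.ndarray, ps: np.ndarray, B: int):
    """Tied parameters -> per-state (mu_k, p_k) arrays of length 2B + 1."""
    if B == 0:
        return mus.copy(), ps.copy()
    mu_k = np.empty(2 * B + 1)
    p_k = np.empty(2 * B + 1)
    for b in range(B):
        mu_k[2 * b] = mu_k[2 * b + 1] = mus[b]
        p_k[2 * b], p_k[2 * b + 1] = ps[b], 1 - ps[b]
    mu_k[-1], p_k[-1] = mus[-1], 0.5
    return mu_k, p_k


@dataclass
class CloneModel:
    labels: np.ndarray  # per-spot clone index
    Z: np.ndarray  # bin x clone state index
    mus: np.ndarray  # tied RDR params (B pairs + balanced anchor)
    ps: np.ndarray  # tied BAF params (< 0.5)
    B: int  # number of mirrored pairs
    tau_bb: float
    phi: float
    t_z: float
    beta: float
    theta: np.ndarray | None
    C: np.ndarray  # per-spot expression normalizer
    bin_ids: np.ndarray  # bins used (after ASE masking), indices into bg
    objective_trace: list = field(default_factory=list)
    normal_clone: int | None = None  # index of pinned always-balanced clone

    @property
    def M(self) -> int:
        return self.Z.shape[1]

    def state_params(self):
        return expand_states(self.mus, self.ps, self.B)

    def clone_profiles(self):
        """Per-clone per-bin (RDR, BAF) implied by the state assignment."""
        mu_k, p_k = self.state_params()
        return mu_k[self.Z], p_k[self.Z]


# -------------------------------------------------------------- emissions


def _effective(mu_k, p_k, th):
    """Tumor/normal-mixed per-(spot, state) RDR and BAF."""
    rdr = th[:, None] * mu_k[None, :] + (1 - th)[:, None]
    baf = (th[:, None] * p_k[None, :] * mu_k[None, :] + 0.5 * (1 - th)[:, None]) / rdr
    return rdr, baf


def emission_loglik(
    X: np.ndarray,
    Y: np.ndarray,
    D: np.ndarray,
    lam: np.ndarray,
    mu_k: np.ndarray,
    p_k: np.ndarray,
    tau_bb: float,
    phi: float,
    theta: np.ndarray | None = None,
    norm: np.ndarray | None = None,
) -> np.ndarray:
    """Per-(spot, bin, state) log-likelihood tensor of shape (N, G, K).

    ``X, Y, D`` are bin x spot; ``norm`` is the per-spot normalizer C_s
    (defaults to sum_j lambda_j, i.e. RDR 1 everywhere).
    """
    G, N = X.shape
    mu_k, p_k = np.asarray(mu_k, float), np.asarray(p_k, float)
    th = np.ones(N) if theta is None else np.asarray(theta, float)
    rdr_eff, baf_eff = _effective(mu_k, p_k, th)
    if not (np.isfinite(rdr_eff).all() and np.isfinite(baf_eff).all()):
        raise ValueError("non-finite effective state parameters")

    T = X.sum(axis=0).astype(float)
    C = np.full(N, lam.sum()) if norm is None else np.asarray(norm, float)
    lam_c = np.maximum(lam, 1e-12)
    mean = T[:, None, None] * lam_c[None, :, None] * rdr_eff[:, None, :] / C[:, None, None]
    mean = np.maximum(mean, 1e-9)
    r = 1.0 / phi
    L = nbinom.logpmf(X.T[:, :, None], r, r / (r + mean))

    a = tau_bb * np.clip(baf_eff, _P_EPS, 1 - _P_EPS)[:, None, :]
    L = L + betabinom.logpmf(Y.T[:, :, None], D.T[:, :, None], a, tau_bb - a)
    return L


def natural_normalizer(lam, mu_k, Z, labels, theta):
    """C_s = sum_j lambda_j RDR_eff(s, Z_{j, l_s}): state means sum to the
    spot total under the current assignment."""
    N = len(labels)
    th = np.ones(N) if theta is None else np.asarray(theta, float)
    base = mu_k[Z][:, labels]  # (G, N)
    rdr_eff = th[None, :] * base + (1 - th)[None, :]
    return (np.maximum(lam, 1e-12)[:, None] * rdr_eff).sum(axis=0)


def _log_trans(K: int, t: float) -> np.ndarray:
    if K == 1:
        return np.zeros((1, 1))
    off = (1 - t) / (K - 1)
    return np.log(np.full((K, K), off) + np.eye(K) * (t - off))


def _chain_logprior(Z, t_z, K, chains, normal_clone=None):
    lp = 0.0
    lt = _log_trans(K, t_z)
    ls = -np.log(K)
    for m in range(Z.shape[1]):
        if normal_clone is not None and m == normal_clone:
            continue
        for ch in chains:
            z = Z[ch, m]
            lp += ls + lt[z[:-1], z[1:]].sum()
    return lp


def _potts(labels, graph: NeighborGraph) -> float:
    tot = 0.0
    for s in range(graph.n_spots):
        same = labels[graph.neighbors[s]] == labels[s]
        tot += float(graph.weights[s][same].sum())
    return tot / 2.0  # each edge counted twice


# ------------------------------------------------------------ fit kernels


class _FitData:
    """Precomputed constants for one fit: counts, baseline, chains."""

    def __init__(self, bg: BinnedGenome, lam, ase_mask):
        self.bin_ids = (
            np.arange(bg.n_bins) if ase_mask is None else np.where(np.asarray(ase_mask))[0]
        )
        self.X = bg.X[self.bin_ids].astype(float)
        self.Y = bg.Y[self.bin_ids].astype(float)
        self.D = bg.D[self.bin_ids].astype(float)
        lam_u = np.asarray(lam, float)[self.bin_ids]
        self.lam = lam_u / lam_u.sum()
        self.T = self.X.sum(axis=0)
        chrom = bg.bins["chrom"].to_numpy()[self.bin_ids]
        self.chains = []
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                self.chains.append(slice(start, i))
                start = i
        self.G, self.N = self.X.shape


def _emissions(model: CloneModel, data: _FitData) -> np.ndarray:
    mu_k, p_k = model.state_params()
    return emission_loglik(
        data.X, data.Y, data.D, data.lam, mu_k, p_k,
        model.tau_bb, model.phi, model.theta, model.C,
    )


def _objective(model: CloneModel, data: _FitData, graph, L=None):
    if L is None:
        L = _emissions(model, data)
    K = L.shape[2]
    emis = 0.0
    cols = np.arange(data.G)
    for m in range(model.M):
        sel = model.labels == m
        if sel.any():
            emis += L[sel][:, cols, model.Z[:, m]].sum()
    return (
        emis
        + _chain_logprior(model.Z, model.t_z, K, data.chains, model.normal_clone)
        + model.beta * _potts(model.labels, graph)
    ), L


def hmm_update(
    L: np.ndarray,
    labels: np.ndarray,
    M: int,
    t_z: float,
    chains: list[slice],
    normal_clone: int | None = None,
    balanced_state: int | None = None,
) -> np.ndarray:
    """Exact MAP state paths per clone given labels and emissions.

    Emissions for clone m are the per-spot log-likelihoods summed over the
    clone's spots; the Viterbi path per chromosome chain maximizes the
    emission + chain-prior term exactly.  Empty clones (and the pinned
    normal clone) receive the balanced state everywhere.
    """
    N, G, K = L.shape
    Z = np.full((G, M), K - 1 if balanced_state is None else balanced_state, dtype=int)
    lt = _log_trans(K, t_z)
    ls = np.full(K, -np.log(K))
    for m in range(M):
        if normal_clone is not None and m == normal_clone:
            continue
        sel = labels == m
        if not sel.any():
            continue
        E = L[sel].sum(axis=0)
        for ch in chains:
            Z[ch, m] = hmm.viterbi(E[ch], lt, ls)
    return Z


def _icm_sweeps(spot_clone_ll, graph, beta, labels, max_sweeps, pinned):
    labels = labels.copy()
    N, M = spot_clone_ll.shape
    for _ in range(max_sweeps):
        changed = False
        for s in range(N):
            if pinned is not None and pinned[s]:
                continue
            score = spot_clone_ll[s].copy()
            nb, wt = graph.neighbors[s], graph.weights[s]
            for m in range(M):
                score[m] += beta * wt[labels[nb] == m].sum()
            new = int(np.argmax(score))
            if score[new] > score[labels[s]]:
                labels[s] = new
                changed = True
        if not changed:
            break
    return labels


def _labeling_objective(spot_clone_ll, graph, beta, labels):
    obj = float(spot_clone_ll[np.arange(len(labels)), labels].sum())
    return obj + beta * _potts(labels, graph)


def hmrf_update(
    spot_clone_ll: np.ndarray,
    graph: NeighborGraph,
    beta: float,
    labels_prev: np.ndarray,
    max_sweeps: int = 20,
    pinned: np.ndarray | None = None,
) -> np.ndarray:
    """Iterated conditional modes on the Potts-form objective.

    ``spot_clone_ll[s, m]`` is the total emission log-likelihood of spot s
    under clone m's state sequence.  Each sweep visits spots in index
    order; ties break toward the lowest clone index; sweeps stop when no
    label changes, each single-spot move non-decreasing in the objective.

    ICM only reaches single-spot-stable labelings, so in addition to the
    previous labels it restarts from every constant labeling and keeps the
    best-objective result; the best is never worse than the from-previous
    run, preserving ascent.
    """
    N, M = spot_clone_ll.shape
    best = _icm_sweeps(spot_clone_ll, graph, beta, labels_prev, max_sweeps, pinned)
    best_obj = _labeling_objective(spot_clone_ll, graph, beta, best)
    for m in range(M):
        init = np.full(N, m, dtype=int)
        if pinned is not None:
            init[pinned] = labels_prev[pinned]
        cand = _icm_sweeps(spot_clone_ll, graph, beta, init, max_sweeps, pinned)
        obj = _labeling_objective(spot_clone_ll, graph, beta, cand)
        if obj > best_obj:
            best, best_obj = cand, obj
    return best


def _masked_ll(x, y, d, t, lam_j, c, th, mu, p, tau, phi):
    """Emission log-likelihood of a flat subset of (spot, bin) cells under
    a single state with parameters (mu, p)."""
    rdr = th * mu + (1 - th)
    baf = (th * p * mu + 0.5 * (1 - th)) / rdr
    mean = np.maximum(t * lam_j * rdr / c, 1e-9)
    r = 1.0 / phi
    ll = nbinom.logpmf(x, r, r / (r + mean)).sum()
    a = tau * np.clip(baf, _P_EPS, 1 - _P_EPS)
    ll += betabinom.logpmf(y, d, a, tau - a).sum()
    return float(ll)


def _optimize_params(model: CloneModel, data: _FitData) -> CloneModel:
    """Coordinate-ascent M-step on hard assignments.

    Each tied parameter (pair BAF p_b, pair RDR mu_b, concentration tau,
    dispersion phi) is refit by bounded 1-D maximization of the emission
    log-likelihood of its assigned cells; a candidate is kept only when it
    improves on the current value, so the joint objective cannot decrease.
    The balanced state stays at (mu = 1, p = 0.5) as the diploid anchor.
    """
    state_of = model.Z[:, model.labels]  # (G, N)
    th_full = np.ones(data.N) if model.theta is None else model.theta
    TH = np.broadcast_to(th_full[None, :], (data.G, data.N))
    TT = np.broadcast_to(data.T[None, :], (data.G, data.N))
    CC = np.broadcast_to(model.C[None, :], (data.G, data.N))
    LJ = np.broadcast_to(data.lam[:, None], (data.G, data.N))

    def cells(mask):
        return (
            data.X[mask], data.Y[mask], data.D[mask],
            TT[mask], LJ[mask], CC[mask], TH[mask],
        )

    def improve(fun, x0, bounds, log=False):
        if log:
            res = minimize_scalar(
                lambda v: -fun(np.exp(v)),
                bounds=(np.log(bounds[0]), np.log(bounds[1])),
                method="bounded", options={"xatol": 1e-3},
            )
            cand = float(np.exp(res.x))
        else:
            res = minimize_scalar(
                lambda v: -fun(v), bounds=bounds, method="bounded",
                options={"xatol": 1e-5},
            )
            cand = float(res.x)
        return cand if -res.fun > fun(x0) else x0

    mus, ps = model.mus.copy(), model.ps.copy()
    if model.B == 0:
        lo = cells(state_of == 0)
        if lo[0].size:
            ps[0] = improve(
                lambda p: _masked_ll(*lo, 1.0, p, model.tau_bb, model.phi),
                ps[0], (_P_EPS, 1 - _P_EPS),
            )
    else:
        for b in range(model.B):
            lo = cells(state_of == 2 * b)
            hi = cells(state_of == 2 * b + 1)

            def pair_ll(mu, p):
                ll = 0.0
                if lo[0].size:
                    ll += _masked_ll(*lo, mu, p, model.tau_bb, model.phi)
                if hi[0].size:
                    ll += _masked_ll(*hi, mu, 1 - p, model.tau_bb, model.phi)
                return ll

            if lo[0].size + hi[0].size == 0:
                continue
            ps[b] = improve(lambda p: pair_ll(mus[b], p), ps[b], (_P_EPS, 0.5))
            mus[b] = improve(lambda m: pair_ll(m, ps[b]), mus[b], _MU_BOUNDS, log=True)
    model = replace(model, mus=mus, ps=ps, objective_trace=model.objective_trace)

    # shared dispersion / concentration over all assigned cells
    mu_k, p_k = model.state_params()
    MU = mu_k[state_of]
    PP = p_k[state_of]
    flat = (
        data.X.ravel(), data.Y.ravel(), data.D.ravel(),
        TT.ravel(), LJ.ravel(), CC.ravel(), TH.ravel(),
    )

    def all_ll(tau, phi):
        rdr = flat[6] * MU.ravel() + (1 - flat[6])
        baf = (flat[6] * PP.ravel() * MU.ravel() + 0.5 * (1 - flat[6])) / rdr
        mean = np.maximum(flat[3] * flat[4] * rdr / flat[5], 1e-9)
        r = 1.0 / phi
        ll = nbinom.logpmf(flat[0], r, r / (r + mean)).sum()
        a = tau * np.clip(baf, _P_EPS, 1 - _P_EPS)
        return float(ll + betabinom.logpmf(flat[1], flat[2], a, tau - a).sum())

    phi = model.phi
    res = minimize_scalar(
        lambda v: -all_ll(model.tau_bb, np.exp(v)),
        bounds=(np.log(1e-4), np.log(2.0)), method="bounded", options={"xatol": 1e-2},
    )
    if -res.fun > all_ll(model.tau_bb, phi):
        phi = float(np.exp(res.x))
    tau = model.tau_bb
    res = minimize_scalar(
        lambda v: -all_ll(np.exp(v), phi),
        bounds=(np.log(2.0), np.log(1e4)), method="bounded", options={"xatol": 1e-2},
    )
    if -res.fun > all_ll(tau, phi):
        tau = float(np.exp(res.x))
    model = replace(model, tau_bb=tau, phi=phi)

    # chain self-transition: closed-form maximizer of the chain prior
    same = total = 0
    for m in range(model.M):
        if model.normal_clone is not None and m == model.normal_clone:
            continue
        for ch in data.chains:
            z = model.Z[ch, m]
            same += int((z[:-1] == z[1:]).sum())
            total += len(z) - 1
    if total > 0:
        model = replace(model, t_z=float(np.clip(same / total, 1e-6, 1 - 1e-6)))
    return model


def _region_grow_init(graph: NeighborGraph, M: int, rng: np.random.Generator) -> np.ndarray:
    """Spatially contiguous random partition by multi-source BFS from M seeds."""
    from collections import deque

    n = graph.n_spots
    labels = np.full(n, -1, dtype=int)
    seeds = rng.choice(n, size=min(M, n), replace=False)
    queues = [deque([int(s)]) for s in seeds]
    for m, s in enumerate(seeds):
        labels[s] = m
    active = True
    while active:
        active = False
        for m, q in enumerate(queues):
            while q:
                s = q.popleft()
                grew = False
                for nb in graph.neighbors[s]:
                    if labels[nb] < 0:
                        labels[nb] = m
                        q.append(int(nb))
                        grew = True
                if grew:
                    active = True
                    break
    labels[labels < 0] = rng.integers(0, M, size=int((labels < 0).sum()))
    return labels


def _ascend(model: CloneModel, data: _FitData, graph, outer_max, tol, pinned, balanced):
    """Run the safeguarded block-coordinate-ascent loop; J non-decreasing."""
    cols = np.arange(data.G)
    J, L = _objective(model, data, graph)
    seen = {}
    for it in range(outer_max):
        model.Z = hmm_update(
            L, model.labels, model.M, model.t_z, data.chains,
            model.normal_clone, balanced,
        )
        cand = _optimize_params(model, data)
        J_cand, L_cand = _objective(cand, data, graph)
        J_cur, L_cur = _objective(model, data, graph)
        if J_cand >= J_cur:
            trace = model.objective_trace
            model = cand
            model.objective_trace = trace
            J, L = J_cand, L_cand
        else:
            J, L = J_cur, L_cur

        # normalizer update (safeguarded)
        mu_k, _ = model.state_params()
        C_new = natural_normalizer(data.lam, mu_k, model.Z, model.labels, model.theta)
        cand = replace(model, C=C_new)
        J_cand, L_cand = _objective(cand, data, graph)
        if J_cand >= J:
            trace = model.objective_trace
            model = cand
            model.objective_trace = trace
            J, L = J_cand, L_cand

        spot_ll = np.stack(
            [L[:, cols, model.Z[:, m]].sum(axis=1) for m in range(model.M)], axis=1
        )
        model.labels = hmrf_update(spot_ll, graph, model.beta, model.labels, pinned=pinned)
        J, L = _objective(model, data, graph)
        model.objective_trace.append(J)
        key = model.labels.tobytes() + model.Z.tobytes()
        if key in seen:
            break  # fixed point or cycle
        seen[key] = J
        if len(model.objective_trace) > 1:
            if J - model.objective_trace[-2] < tol * max(1.0, abs(J)):
                break
    return model


def fit(
    bg: BinnedGenome,
    lam: np.ndarray,
    graph: NeighborGraph,
    M_init: int = 3,
    n_states: int = 7,
    theta: np.ndarray | None = None,
    beta: float = 2.0,
    seed: int = 0,
    outer_max: int = 15,
    tol: float = 1e-5,
    ase_mask: np.ndarray | None = None,
    add_normal_clone: bool = False,
    n_restarts: int = 3,
) -> CloneModel:
    """Block coordinate ascent for clone labels, states, and latent (mu, p).

    Labels initialize as spatially contiguous random partitions (seeded
    region growing); ``n_restarts`` independent initializations are run
    (seeds derived deterministically from ``seed``) and the best joint
    objective wins.  With ``theta`` given, spots with theta < 0.5 are
    pinned to a dedicated balanced normal clone; with ``add_normal_clone``
    and no theta, the normal clone exists but spots move freely in and out
    of it.
    """
    if M_init < 1:
        raise ValueError("M_init >= 1 required")
    data = _FitData(bg, lam, ase_mask)
    mus, ps, B = make_states(n_states)
    K = len(expand_states(mus, ps, B)[0])
    balanced = K - 1

    normal_clone = None
    M = M_init
    pinned = None
    if theta is not None:
        normal_clone = 0
        M = M_init + 1
        pinned = np.asarray(theta) < 0.5
    elif add_normal_clone:
        normal_clone = 0
        M = M_init + 1

    best = None
    for r in range(max(n_restarts, 1)):
        rng = np.random.default_rng(seed * 1000 + r)
        labels = _region_grow_init(graph, M, rng)
        if pinned is not None:
            labels[pinned] = normal_clone
        model = CloneModel(
            labels=labels,
            Z=np.full((data.G, M), balanced, dtype=int),
            mus=mus.copy(), ps=ps.copy(), B=B,
            tau_bb=30.0, phi=0.1, t_z=0.95, beta=beta,
            theta=None if theta is None else np.asarray(theta, float),
            C=np.ones(data.N) * data.lam.sum(),
            bin_ids=data.bin_ids, normal_clone=normal_clone,
        )
        model = _ascend(model, data, graph, outer_max, tol, pinned, balanced)
        if best is None or model.objective_trace[-1] > best.objective_trace[-1]:
            best = model
    model = best

    # drop empty clones (keep the normal clone when pinned)
    occupied = np.array(
        [(model.labels == m).any() or m == model.normal_clone for m in range(model.M)]
    )
    if not occupied.all():
        remap = -np.ones(model.M, dtype=int)
        remap[occupied] = np.arange(occupied.sum())
        warnings.warn(f"dropping {int((~occupied).sum())} empty clone(s)")
        model.Z = model.Z[:, occupied]
        model.labels = remap[model.labels]
        if model.normal_clone is not None:
            model.normal_clone = int(remap[model.normal_clone])
    return model


def merge_clones(
    model: CloneModel,
    bg: BinnedGenome,
    lam: np.ndarray,
    graph: NeighborGraph,
    sim_threshold: float = 0.05,
    refit_iters: int = 3,
) -> CloneModel:
    """Merge clones whose implied per-bin (RDR, BAF) profiles nearly agree.

    The dissimilarity of two clones is the fraction of bins whose
    state-implied (mu, p) differ; pairs below ``sim_threshold`` merge
    (union of spots), and the model is refit briefly after each merge.
    """
    data = _FitData(bg, lam, np.isin(np.arange(bg.n_bins), model.bin_ids))
    while model.M > 1:
        rdr, baf = model.clone_profiles()
        best = None
        for a in range(model.M):
            for b in range(a + 1, model.M):
                if model.normal_clone in (a, b):
                    continue  # the pinned normal clone never merges
                diff = (np.abs(rdr[:, a] - rdr[:, b]) > 0.05) | (
                    np.abs(baf[:, a] - baf[:, b]) > 0.05
                )
                frac = diff.mean()
                if frac < sim_threshold and (best is None or frac < best[0]):
                    best = (frac, a, b)
        if best is None:
            break
        _, a, b = best
        keep = [m for m in range(model.M) if m != b]
        remap = -np.ones(model.M, dtype=int)
        remap[keep] = np.arange(len(keep))
        remap[b] = remap[a]
        model = replace(
            model,
            labels=remap[model.labels],
            Z=model.Z[:, keep],
            normal_clone=None if model.normal_clone is None else int(remap[model.normal_clone]),
            objective_trace=list(model.objective_trace),
        )
        pinned = None
        if model.theta is not None and model.normal_clone is not None:
            pinned = model.theta < 0.5
        balanced = len(model.state_params()[0]) - 1
        model = _ascend(model, data, graph, refit_iters, 0.0, pinned, balanced)
    return model
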