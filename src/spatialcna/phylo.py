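"""Clone phylogeny from LOH markers and spatial placement of ancestors.

Complete loss of one parental haplotype over a segment is irreversible:
once lost in a lineage it cannot be regained.  Such LOH segments therefore
act as binary phylogenetic characters under a star homoplasy model — a
marker may be gained independently on several branches but never lost.
The minimum-gain rooted tree over the clones (root = LOH-free normal
ancestor) is found exactly by enumerating rooted binary topologies (with
branch-and-bound pruning for larger clone sets).  Mirrored losses (A lost
in one clone, B in another over the same segment) are distinct characters.

Leaves are projected to the centroid of their spots; ancestor locations
maximize a Gaussian diffusion likelihood in which the displacement along
each edge has variance proportional to the number of markers gained on it
(s_v ~ N(s_parent, w I)), a positive-definite linear system whose solution
makes every internal node the precision-weighted average of its tree
neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import count

import networkx as nx
import numpy as np
import pandas as pd

from .integer_cn import IntegerCN

__all__ = [
    "LOHMarkerMatrix",
    "extract_loh_markers",
    "build_tree",
    "clone_centroids",
    "place_ancestors",
    "tree_to_newick",
]

EPS_WEIGHT = 0.5  # diffusion variance for zero-gain edges


@dataclass
class LOHMarkerMatrix:
    presence: np.ndarray  # clone x marker, bool
    meta: pd.DataFrame  # chrom, first_bin, last_bin, n_bins, lost, support

    @property
    def n_markers(self) -> int:
        return self.presence.shape[1]

    @property
    def n_clones(self) -> int:
        return self.presence.shape[0]


def extract_loh_markers(
    cn: IntegerCN,
    bins: pd.DataFrame,
    D: np.ndarray,
    labels: np.ndarray,
    min_bins: int = 3,
    min_umis: int = 100,
    clone_ids: list | None = None,
) -> LOHMarkerMatrix:
    """Binary LOH characters from integer copy numbers.

    A marker is a maximal run of bins, within one chromosome, over which
    the set of clones having lost a given haplotype is constant and
    nonempty.  Markers shorter than ``min_bins`` bins are dropped; a clone
    carries a marker only if its spots contribute at least ``min_umis``
    SNP-covering UMIs over the run.  ``D`` is bin x spot total allele
    counts aligned with ``cn`` rows; ``labels`` are per-spot clone indices.
    """
    G, M = cn.A.shape
    clone_ids = list(range(M)) if clone_ids is None else clone_ids
    chrom = bins["chrom"].to_numpy()
    clone_D = np.stack([D[:, labels == m].sum(axis=1) for m in range(M)], axis=1)

    records, presences = [], []
    for hap, lost_mat in (("B", cn.B == 0), ("A", cn.A == 0)):
        start = 0
        for j in range(1, G + 1):
            boundary = (
                j == G
                or chrom[j] != chrom[start]
                or (lost_mat[j] != lost_mat[start]).any()
            )
            if not boundary:
                continue
            run = slice(start, j)
            pattern = lost_mat[start].copy()
            n_bins = j - start
            if pattern.any() and n_bins >= min_bins:
                support = clone_D[run].sum(axis=0)
                carriers = pattern & (support >= min_umis)
                if carriers.any():
                    records.append(
                        {
                            "chrom": chrom[start],
                            "first_bin": start,
                            "last_bin": j - 1,
                            "n_bins": n_bins,
                            "lost": hap,
                            "support": int(support[carriers].sum()),
                        }
                    )
                    presences.append(carriers)
            start = j
    if not records:
        warnings.warn("no LOH markers pass the filters; tree building unavailable")
        return LOHMarkerMatrix(
            presence=np.zeros((M, 0), bool),
            meta=pd.DataFrame(
                columns=["chrom", "first_bin", "last_bin", "n_bins", "lost", "support"]
            ),
        )
    return LOHMarkerMatrix(
        presence=np.stack(presences, axis=1), meta=pd.DataFrame(records)
    )


# ------------------------------------------------------------- parsimony


def _insertions(tree, leaf):
    """All ways to attach ``leaf`` onto an edge of (or above) ``tree``."""
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insertions(left, leaf):
            yield (t, right)
        for t in _insertions(right, leaf):
            yield (left, t)


def _nodes_with_leafsets(tree):
    """Post-order list of (node, leafset, parent_leafset-or-None)."""
    out = []

    def rec(node, parent_set):
        if isinstance(node, tuple):
            ls = rec(node[0], None) | rec(node[1], None)
        else:
            ls = frozenset([node])
        out.append((node, ls, parent_set))
        return ls

    # second pass to record parents properly
    out.clear()

    def rec2(node):
        if isinstance(node, tuple):
            l_ls = rec2(node[0])
            r_ls = rec2(node[1])
            ls = l_ls | r_ls
        else:
            ls = frozenset([node])
        out.append((node, ls))
        return ls

    rec2(tree)
    sets = {id(n): ls for n, ls in out}
    parents = {id(tree): None}

    def rec3(node):
        if isinstance(node, tuple):
            parents[id(node[0])] = sets[id(node)]
            parents[id(node[1])] = sets[id(node)]
            rec3(node[0])
            rec3(node[1])

    rec3(tree)
    return [(n, ls, parents[id(n)]) for n, ls in out]


def _score_tree(tree, marker_sets) -> tuple[int, list[list]]:
    """Minimum star-homoplasy gains and per-marker gain nodes.

    A marker with carrier set S is gained exactly at every maximal node
    whose leafset is contained in S (the parent's leafset is not).
    """
    info = _nodes_with_leafsets(tree)
    total, gain_nodes = 0, []
    for S in marker_sets:
        nodes = [
            ls
            for _, ls, pls in info
            if ls <= S and ls and (pls is None or not pls <= S)
        ]
        total += len(nodes)
        gain_nodes.append(nodes)
    return total, gain_nodes


def _enumerate_trees(leaves: list[int], marker_sets, bnb: bool):
    """Yield (score, tree) for candidate topologies, exact minimum guaranteed.

    With ``bnb`` the partial-tree score prunes the insertion search
    (restricting a tree to a leaf subset never increases the gain count,
    so the partial score is a valid lower bound).
    """
    best = [np.inf, None]

    def rec(tree, remaining):
        if bnb:
            restricted = [S & frozenset(_leaves(tree)) for S in marker_sets]
            sc, _ = _score_tree(tree, [S for S in restricted if S])
            if sc >= best[0]:
                return
        if not remaining:
            sc, _ = _score_tree(tree, marker_sets)
            if sc < best[0]:
                best[0], best[1] = sc, tree
            return
        leaf, rest = remaining[0], remaining[1:]
        for t in _insertions(tree, leaf):
            rec(t, rest)

    if len(leaves) == 1:
        return 0 if not marker_sets else sum(1 for S in marker_sets if S), leaves[0]
    rec((leaves[0], leaves[1]), leaves[2:])
    return best[0], best[1]


def _leaves(tree):
    if isinstance(tree, tuple):
        return _leaves(tree[0]) + _leaves(tree[1])
    return [tree]


def _greedy_tree(leaves, marker_sets):
    """Agglomerative fallback for large clone sets: join the pair sharing
    the most markers, repeatedly."""
    forest = {m: frozenset([m]) for m in leaves}
    trees = {m: m for m in leaves}
    while len(trees) > 1:
        keys = sorted(trees)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                shared = sum(
                    1 for S in marker_sets if forest[a] <= S and forest[b] <= S
                )
                if best is None or shared > best[0]:
                    best = (shared, a, b)
        _, a, b = best
        trees[a] = (trees[a], trees[b])
        forest[a] = forest[a] | forest[b]
        del trees[b], forest[b]
    return next(iter(trees.values()))


def build_tree(markers: LOHMarkerMatrix, exact_limit: int = 7, bnb_limit: int = 10):
    """Minimum-gain clone tree under star homoplasy.

    Returns a rooted ``networkx.DiGraph`` (root node ``"root"`` is the
    LOH-free normal ancestor) with node attribute ``clone`` and edge
    attributes ``weight`` (marker gains) and ``markers``.  Clone leaves
    whose pendant edge gains no marker are contracted into their parent —
    such a clone has no unique losses and is reported as an ancestor of
    its sister clones.
    """
    M = markers.n_clones
    leaves = list(range(M))
    marker_sets = [
        frozenset(np.where(markers.presence[:, c])[0]) for c in range(markers.n_markers)
    ]
    if M == 0:
        raise ValueError("no clones")
    if M == 1:
        g = nx.DiGraph()
        g.add_node("root", clone=None)
        g.add_node("c0", clone=0)
        mk = [c for c, S in enumerate(marker_sets) if S]
        g.add_edge("root", "c0", weight=len(mk), markers=mk)
        return g, len(mk)

    if M <= exact_limit:
        score, tree = _enumerate_trees(leaves, marker_sets, bnb=False)
    elif M <= bnb_limit:
        score, tree = _enumerate_trees(leaves, marker_sets, bnb=True)
    else:
        warnings.warn("more than 10 clones: greedy topology, not guaranteed minimal")
        tree = _greedy_tree(leaves, marker_sets)
        score, _ = _score_tree(tree, marker_sets)

    _, gain_nodes = _score_tree(tree, marker_sets)
    # materialize as a DiGraph hanging from the normal root
    g = nx.DiGraph()
    g.add_node("root", clone=None)
    ids = count()
    name_of = {}

    def rec(node, parent_name):
        if isinstance(node, tuple):
            name = f"v{next(ids)}"
            g.add_node(name, clone=None)
        else:
            name = f"c{node}"
            g.add_node(name, clone=int(node))
        ls = frozenset(_leaves(node)) if isinstance(node, tuple) else frozenset([node])
        name_of[ls] = name
        mk = [c for c, nodes in enumerate(gain_nodes) if ls in nodes]
        g.add_edge(parent_name, name, weight=len(mk), markers=mk)
        if isinstance(node, tuple):
            rec(node[0], name)
            rec(node[1], name)

    rec(tree, "root")

    # Contract a clone leaf with no unique gains into its parent when a
    # sibling subtree does carry gains: the clone's marker set is a strict
    # subset of its sister's, so the clone is reported as the ancestor.
    # Identical-profile siblings (both pendant weights 0) stay siblings.
    def _subtree_weight(node):
        return sum(g.edges[e]["weight"] for e in nx.dfs_edges(g, node)) + sum(
            g.edges[p, node]["weight"] for p in g.predecessors(node)
        )

    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.out_degree(n) == 0 and g.nodes[n]["clone"] is not None:
                parent = next(g.predecessors(n))
                if parent == "root" or g.nodes[parent]["clone"] is not None:
                    continue
                sibs = [c for c in g.successors(parent) if c != n]
                if g.edges[parent, n]["weight"] == 0 and any(
                    _subtree_weight(c) > 0 for c in sibs
                ):
                    g.nodes[parent]["clone"] = g.nodes[n]["clone"]
                    g.remove_node(n)
                    changed = True
    return g, score


def clone_centroids(
    labels: np.ndarray,
    S: np.ndarray,
    slice_id: np.ndarray | None = None,
    z_offsets: dict | None = None,
) -> dict[int, np.ndarray]:
    """Mean spot coordinate per clone; 3D when per-slice z offsets are given."""
    coords = np.asarray(S, float)
    if z_offsets is not None:
        z = np.array([z_offsets[s] for s in slice_id], float)
        coords = np.column_stack([coords, z])
    out = {}
    for m in np.unique(labels):
        sel = labels == m
        out[int(m)] = coords[sel].mean(axis=0)
    return out


def place_ancestors(
    g: nx.DiGraph,
    leaf_locations: dict[str, np.ndarray],
    eps: float = EPS_WEIGHT,
) -> dict[str, np.ndarray]:
    """Maximum-likelihood ancestor locations under edge-variance diffusion.

    Solves the stationarity system in which each free node is the
    precision-weighted (1/w) average of its tree neighbors, with leaves
    clamped at their centroids and zero-gain edges given variance ``eps``.
    """
    if not nx.is_weakly_connected(g):
        raise ValueError("tree is disconnected")
    free = [n for n in g.nodes if n not in leaf_locations]
    if not free:
        return dict(leaf_locations)
    dim = len(next(iter(leaf_locations.values())))
    idx = {n: i for i, n in enumerate(free)}
    A = np.zeros((len(free), len(free)))
    rhs = np.zeros((len(free), dim))
    und = g.to_undirected()
    for n in free:
        i = idx[n]
        for nb in und.neighbors(n):
            w = max(und.edges[n, nb].get("weight", 0), 0) or eps
            prec = 1.0 / w
            A[i, i] += prec
            if nb in idx:
                A[i, idx[nb]] -= prec
            else:
                rhs[i] += prec * np.asarray(leaf_locations[nb], float)
    sol = np.linalg.solve(A, rhs)
    out = {n: np.asarray(v, float) for n, v in leaf_locations.items()}
    for n, i in idx.items():
        out[n] = sol[i]
    return out


def tree_to_newick(g: nx.DiGraph) -> str:
    """Newick string with edge weights as branch lengths."""

    def rec(n):
        children = list(g.successors(n))
        label = f"clone{g.nodes[n]['clone']}" if g.nodes[n]["clone"] is not None else n
        if not children:
            return label
        inner = ",".join(
            f"{rec(c)}:{g.edges[n, c]['weight']}" for c in children
        )
        return f"({inner}){label}"

    return rec("root") + ";"
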