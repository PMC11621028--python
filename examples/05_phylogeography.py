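"""Build a clone phylogeny from irreversible LOH markers and place
ancestors in physical space by Gaussian diffusion.

Clone profiles are generated by dropping LOH segments along a random tree;
the star-homoplasy parsimony search recovers a minimum-gain tree, leaves
are projected to clone centroids, and internal nodes solve the
precision-weighted-average system (edge variance = marker gains).
"""

import numpy as np
import pandas as pd

import spatialcna as sc
from spatialcna.phylo import tree_to_newick

profiles, generating_tree = sc.simulate_tree_profiles(M=4, n_loh=6, seed=2)
A, B = profiles[:, :, 0], profiles[:, :, 1]
G = A.shape[0]

# spots: 30 per clone on separated patches
rng = np.random.default_rng(0)
labels = np.repeat(np.arange(4), 30)
centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
S = centers[labels] + rng.normal(scale=1.0, size=(120, 2))
D = np.full((G, 120), 40)

bins = pd.DataFrame({"chrom": "chr1", "start": np.arange(G), "end": np.arange(G) + 1})
cn = sc.IntegerCN(A=A, B=B, ploidy_scale=2.0, state_A=np.array([]), state_B=np.array([]))
markers = sc.extract_loh_markers(cn, bins, D, labels, min_bins=3, min_umis=100)
print(f"{markers.n_markers} LOH markers pass the filters "
      f"(>= 3 bins, >= 100 supporting UMIs per carrying clone)")

tree, score = sc.build_tree(markers)
print(f"minimum-gain tree: {score} total gains")
print("newick:", tree_to_newick(tree))

cents = sc.clone_centroids(labels, S)
leaf_locs = {n: cents[d["clone"]] for n, d in tree.nodes(data=True)
             if d["clone"] is not None and tree.out_degree(n) == 0}
locs = sc.place_ancestors(tree, leaf_locs)
for n in tree.nodes:
    kind = ("clone " + str(tree.nodes[n]["clone"])
            if tree.nodes[n]["clone"] is not None else "ancestor")
    print(f"  {n:>5} ({kind:>9}) at {np.round(locs[n], 2)}")
print("ancestors sit at precision-weighted averages of their tree neighbors")
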