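"""End-to-end orchestration: filters -> phasing/binning -> baseline ->
optional purity -> clone/CNA inference -> integer copies -> phylogeography.

Each stage writes a file checkpoint into the output directory so stages
can be inspected or rerun individually; a run manifest records the
configuration, seed, and per-stage outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import baseline, clones, integer_cn, phasing, phylo, purity
from .io import RawBundle, filter_genes, filter_snps, filter_spots

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    min_umi: int = 50
    min_snp_umi: int = 50
    min_frac_spots: float = 0.005
    k_phase: int = 5
    min_bin_total: int = 300
    n_normal_clusters: int = 5
    ase_alpha: float = 0.05
    loh_threshold: float = 0.2
    estimate_purity: bool = False
    M_init: int = 5
    n_states: int = 7
    beta: float = 2.0
    k_spatial: int = 6
    max_cn: int = 6
    phylo_min_bins: int = 3
    phylo_min_umis: int = 100
    outer_max: int = 15
    seed: int = 0
    z_offsets: dict | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class PipelineResult:
    bundle: RawBundle
    binned: phasing.BinnedGenome
    lam: np.ndarray
    normal_mask: np.ndarray
    ase_mask: np.ndarray
    theta: np.ndarray | None
    model: clones.CloneModel
    cn: integer_cn.IntegerCN
    events: pd.DataFrame
    tree: object | None
    locations: dict | None
    manifest: dict = field(default_factory=dict)


def _save_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=1, default=str))


def run_pipeline(
    bundle: RawBundle,
    config: PipelineConfig | None = None,
    out_dir=None,
    W: dict | None = None,
) -> PipelineResult:
    """Run all stages on a loaded bundle; optionally checkpoint to ``out_dir``."""
    config = config or PipelineConfig()
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "stages": {}}

    def stage(name):
        manifest["stages"][name] = {"t_start": time.time()}

    def done(name, **info):
        manifest["stages"][name]["runtime_s"] = round(
            time.time() - manifest["stages"][name].pop("t_start"), 3
        )
        manifest["stages"][name].update(info)

    stage("filter")
    bundle, rep_s = filter_spots(bundle, config.min_umi, config.min_snp_umi)
    bundle, rep_g = filter_genes(bundle, config.min_frac_spots)
    bundle, rep_p = filter_snps(bundle)
    done("filter", spots=bundle.n_spots, genes=bundle.n_genes, snps=bundle.n_snps,
         removed=[rep_s.summary(), rep_g.summary(), rep_p.summary()])

    stage("phase_bin")
    pb = phasing.pseudobulk(bundle)
    _, assign = phasing.fit_phasing_hmm(pb, K_phase=config.k_phase)
    bins = phasing.make_bins(bundle.snp_index, pb, config.min_bin_total)
    bg = phasing.aggregate(bundle, assign, bins)
    done("phase_bin", n_bins=bg.n_bins)
    if out:
        bg.bins.to_csv(out / "bins.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "chrom": bundle.snp_index["chrom"],
                "pos": bundle.snp_index["pos"],
                "h": assign.h,
                "z": assign.z,
                "posterior_h1": assign.posterior_h1,
            }
        ).to_csv(out / "phase.tsv", sep="\t", index=False)

    stage("baseline")
    normal_mask = baseline.identify_normal_spots(
        bg, n_clusters=min(config.n_normal_clusters, bg.n_spots),
        random_state=config.seed,
    )
    lam = baseline.compute_baseline(bg, normal_mask)
    ase_mask = baseline.filter_ase_bins(bg, normal_mask, config.ase_alpha)
    done("baseline", n_normal=int(normal_mask.sum()), bins_masked=int((~ase_mask).sum()))

    theta = None
    if config.estimate_purity:
        stage("purity")
        loh = purity.detect_loh(bg, config.loh_threshold, lam=lam)
        if len(loh):
            tp = purity.estimate_theta(bg, loh)
            theta = tp.theta
            normal_mask = baseline.identify_normal_spots(bg, theta=theta)
            lam = baseline.compute_baseline(bg, normal_mask) if normal_mask.any() else lam
            done("purity", n_loh_bins=len(loh), mu=loh.mu)
            if out:
                pd.DataFrame(
                    {"barcode": bg.barcodes, "theta": theta, "f": tp.f, "support": tp.support}
                ).to_csv(out / "purity.tsv", sep="\t", index=False)
        else:
            done("purity", n_loh_bins=0)

    stage("clones")
    graph = clones.build_graph(bg.S, bg.slice_id, W=W, k_spatial=config.k_spatial)
    model = clones.fit(
        bg, lam, graph, M_init=config.M_init, n_states=config.n_states,
        theta=theta, beta=config.beta, seed=config.seed,
        outer_max=config.outer_max, ase_mask=ase_mask,
        add_normal_clone=theta is None,
    )
    model = clones.merge_clones(model, bg, lam, graph)
    done("clones", M=model.M, objective=model.objective_trace[-1] if model.objective_trace else None)
    if out:
        pd.DataFrame({"barcode": bg.barcodes, "clone": model.labels}).to_csv(
            out / "clones.tsv", sep="\t", index=False
        )

    stage("integer_cn")
    mu_k, p_k = model.state_params()
    cn = integer_cn.assign_integer_cn(mu_k, p_k, model.Z, max_cn=config.max_cn)
    events = integer_cn.classify_events(cn, bg.bins.iloc[model.bin_ids].reset_index(drop=True))
    done("integer_cn", ploidy_scale=cn.ploidy_scale)
    if out:
        events.to_csv(out / "events.tsv", sep="\t", index=False)

    stage("phylogeography")
    tree, locations = None, None
    tumor_clones = [m for m in range(model.M) if m != model.normal_clone]
    if len(tumor_clones) >= 1:
        sub_cols = np.array(tumor_clones)
        sub_cn = integer_cn.IntegerCN(
            A=cn.A[:, sub_cols], B=cn.B[:, sub_cols],
            ploidy_scale=cn.ploidy_scale, state_A=cn.state_A, state_B=cn.state_B,
        )
        relabel = -np.ones(model.M, int)
        relabel[sub_cols] = np.arange(len(sub_cols))
        tumor_labels = relabel[model.labels]
        markers = phylo.extract_loh_markers(
            sub_cn, bg.bins.iloc[model.bin_ids].reset_index(drop=True),
            bg.D[model.bin_ids], tumor_labels,
            min_bins=config.phylo_min_bins, min_umis=config.phylo_min_umis,
        )
        if markers.n_markers > 0:
            tree, score = phylo.build_tree(markers)
            keep = tumor_labels >= 0
            cents = phylo.clone_centroids(
                tumor_labels[keep], bg.S[keep], bg.slice_id[keep], config.z_offsets
            )
            leaf_locs = {}
            for n, data in tree.nodes(data=True):
                if data["clone"] is not None and data["clone"] in cents:
                    leaf_locs[n] = cents[data["clone"]]
            locations = phylo.place_ancestors(tree, leaf_locs)
            done("phylogeography", n_markers=markers.n_markers, parsimony=score)
            if out:
                (out / "tree.nwk").write_text(phylo.tree_to_newick(tree))
                _save_json(out / "locations.json", {k: list(v) for k, v in locations.items()})
        else:
            done("phylogeography", n_markers=0)
    else:
        done("phylogeography", n_markers=0)

    if out:
        _save_json(out / "manifest.json", manifest)
    return PipelineResult(
        bundle=bundle, binned=bg, lam=lam, normal_mask=normal_mask,
        ase_mask=ase_mask, theta=theta, model=model, cn=cn, events=events,
        tree=tree, locations=locations, manifest=manifest,
    )
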