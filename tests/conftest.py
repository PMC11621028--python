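import numpy as np
import pandas as pd
import pytest

from spatialcna import (
    RawBundle,
    SimConfig,
    aggregate,
    compute_baseline,
    filter_spots,
    fit_phasing_hmm,
    make_bins,
    pseudobulk,
    simulate,
)


@pytest.fixture(scope="session")
def small_sim():
    """64-spot, 40-bin, 3-clone simulation with normal admixture."""
    cfg = SimConfig(
        nx=8, ny=8, n_bins=40, umi_per_spot=1200, allele_umi_per_spot=250,
        normal_fraction=0.2, seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_binned(small_sim):
    """Phased + binned version of the small simulation."""
    bundle, gt = small_sim
    bundle, _ = filter_spots(bundle)
    pb = pseudobulk(bundle)
    _, assign = fit_phasing_hmm(pb, K_phase=4, max_iter=15)
    bins = make_bins(bundle.snp_index, pb, min_total=300)
    bg = aggregate(bundle, assign, bins)
    return bg, gt, assign, bundle


@pytest.fixture
def tiny_bundle():
    """Handmade 4-gene, 6-SNP, 5-spot bundle for filter unit tests."""
    rng = np.random.default_rng(0)
    X0 = rng.integers(10, 40, size=(4, 5))
    D0 = rng.integers(15, 30, size=(6, 5))
    Y0 = rng.binomial(D0, 0.5)
    gene_index = pd.DataFrame(
        {
            "gene": ["gA", "gB", "gC", "gD"],
            "chrom": ["chr1", "chr1", "chr2", "chr2"],
            "start": [100, 5000, 100, 5000],
            "end": [2000, 7000, 2000, 7000],
            "ig": False,
            "hla": [False, False, False, True],
        }
    )
    snp_index = pd.DataFrame(
        {
            # one SNP in each gene, one intergenic, one in the HLA gene
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2", "chr2"],
            "pos": [500, 3000, 6000, 500, 6000, 9000],
            "phase_flag": 0,
        }
    )
    return RawBundle(
        X0=X0, Y0=Y0, D0=D0,
        S=rng.uniform(0, 10, size=(5, 2)),
        slice_id=np.array(["s0"] * 5),
        barcodes=np.array([f"b{i}" for i in range(5)]),
        snp_index=snp_index,
        gene_index=gene_index,
    )


@pytest.fixture(scope="session")
def baseline_small(small_binned):
    bg, gt, _, _ = small_binned
    # all spots survive the UMI filters at this depth, so truth aligns
    normal = gt.labels == -1
    lam = compute_baseline(bg, normal)
    return lam, normal
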