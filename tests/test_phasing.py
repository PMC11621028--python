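import numpy as np
import pandas as pd
import pytest

from spatialcna import (
    SimConfig,
    aggregate,
    fit_phasing_hmm,
    make_bins,
    pseudobulk,
    simulate,
)
from spatialcna import hmm
from spatialcna.phasing import (
    HAP1,
    HAP2,
    PhaseAssignment,
    PhasingModel,
    PseudobulkAlleles,
    _emission_matrix,
    phasing_emission_loglik,
)


class TestPseudobulk:
    def test_row_sums(self, tiny_bundle):
        pb = pseudobulk(tiny_bundle)
        np.testing.assert_array_equal(pb.y0, tiny_bundle.Y0.sum(axis=1))
        np.testing.assert_array_equal(pb.d0, tiny_bundle.D0.sum(axis=1))

    def test_single_spot_identity(self, tiny_bundle):
        one = tiny_bundle.subset(spots=[2])
        pb = pseudobulk(one)
        np.testing.assert_array_equal(pb.y0, tiny_bundle.Y0[:, 2])


class TestEmission:
    def test_symmetric_at_half(self):
        for y, d in [(0, 4), (3, 7), (5, 5)]:
            assert phasing_emission_loglik(y, d, HAP1, 0.5, 25.0) == pytest.approx(
                phasing_emission_loglik(y, d, HAP2, 0.5, 25.0)
            )

    def test_empty_observation_is_certain(self):
        assert phasing_emission_loglik(0, 0, HAP1, 0.2, 10.0) == pytest.approx(0.0)

    def test_matches_numeric_integration(self):
        # Beta-binomial pmf as the binomial marginalized over a Beta prior,
        # computed on a fine grid, independent of scipy's implementation.
        from scipy.stats import beta as beta_dist, binom

        y, d, p, tau = 2, 10, 0.1, 20.0
        grid = np.linspace(1e-6, 1 - 1e-6, 200_001)
        dens = beta_dist.pdf(grid, tau * p, tau * (1 - p)) * binom.pmf(y, d, grid)
        expected = np.trapezoid(dens, grid)
        got = np.exp(phasing_emission_loglik(y, d, HAP1, p, tau))
        assert got == pytest.approx(expected, rel=1e-4)
        # haplotype 2 swaps the shape parameters
        got2 = np.exp(phasing_emission_loglik(d - y, d, HAP2, p, tau))
        assert got2 == pytest.approx(expected, rel=1e-4)

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            phasing_emission_loglik(5, 3, HAP1, 0.2, 10.0)
        with pytest.raises(ValueError):
            phasing_emission_loglik(1, 3, HAP1, 1.5, 10.0)


class TestFitPhasingHMM:
    def test_loglik_monotone_and_forward_exact(self):
        # forward likelihood of the fitted joint chain equals brute-force
        # path enumeration on a 6-SNP chain with 2 BAF clusters (4 states)
        rng = np.random.default_rng(1)
        d = rng.integers(10, 30, size=6)
        y = rng.binomial(d, 0.3)
        pb = PseudobulkAlleles(y0=y, d0=d, chrom=np.array(["chr1"] * 6))
        model, _ = fit_phasing_hmm(pb, K_phase=2, max_iter=8)
        tr = np.array(model.loglik_trace)
        assert np.all(np.diff(tr) >= -1e-8 * np.abs(tr[0]))
        E = _emission_matrix(y.astype(float), d.astype(float), model.p, model.tau)
        _, ll = hmm.forward(E, model.joint_log_trans(), model.joint_log_start())
        assert ll == pytest.approx(
            hmm.enumerate_loglik(E, model.joint_log_trans(), model.joint_log_start()),
            rel=1e-10,
        )

    def test_phase_unidentifiable_when_balanced(self):
        rng = np.random.default_rng(2)
        d = rng.integers(30, 60, size=50)
        y = rng.binomial(d, 0.5)
        pb = PseudobulkAlleles(y0=y, d0=d, chrom=np.array(["chr1"] * 50))
        init = PhasingModel(p=np.array([0.5]), tau=30.0, t=0.999, q=0.99)
        _, assign = fit_phasing_hmm(pb, K_phase=1, init=init, max_iter=3)
        np.testing.assert_allclose(assign.posterior_h1, 0.5, atol=1e-9)

    def test_planted_switch_errors_corrected(self):
        # 200 SNPs, half the genome at BAF 0.2, block switch errors
        prof = np.ones((25, 1, 2), int)
        prof[:13, 0, :] = (4, 1)  # BAF 0.2
        cfg = SimConfig(nx=7, ny=7, M=1, n_bins=25, snps_per_bin=8,
                        clone_profiles=prof, allele_umi_per_spot=250,
                        switch_rate=0.03, seed=7)
        bundle, gt = simulate(cfg)
        pb = pseudobulk(bundle)
        _, assign = fit_phasing_hmm(pb, K_phase=3, max_iter=20)
        imb = gt.snp_bin < 13
        acc = max(
            (assign.h[imb] == gt.h_flip[imb]).mean(),
            (assign.h[imb] != gt.h_flip[imb]).mean(),
        )
        assert acc >= 0.95


class TestMakeBins:
    def test_greedy_accumulation(self):
        pb = PseudobulkAlleles(
            y0=np.zeros(4, int), d0=np.array([5, 5, 5, 5]),
            chrom=np.array(["chr1"] * 4),
        )
        idx = pd.DataFrame({"chrom": pb.chrom, "pos": [10, 20, 30, 40]})
        bins = make_bins(idx, pb, min_total=10)
        assert [b["snps"] for b in bins] == [[0, 1], [2, 3]]

    def test_trailing_deficient_bin(self):
        pb = PseudobulkAlleles(
            y0=np.zeros(3, int), d0=np.array([5, 5, 3]), chrom=np.array(["chr1"] * 3)
        )
        idx = pd.DataFrame({"chrom": pb.chrom, "pos": [1, 2, 3]})
        bins = make_bins(idx, pb, min_total=10)
        assert [b["snps"] for b in bins] == [[0, 1], [2]]

    def test_min_total_one_gives_singletons(self):
        pb = PseudobulkAlleles(
            y0=np.zeros(5, int), d0=np.ones(5, int), chrom=np.array(["chr1"] * 5)
        )
        idx = pd.DataFrame({"chrom": pb.chrom, "pos": np.arange(5) + 1})
        bins = make_bins(idx, pb, min_total=1)
        assert len(bins) == 5

    def test_chromosomes_do_not_mix(self):
        pb = PseudobulkAlleles(
            y0=np.zeros(4, int), d0=np.array([5, 3, 5, 3]),
            chrom=np.array(["chr1", "chr1", "chr2", "chr2"]),
        )
        idx = pd.DataFrame({"chrom": pb.chrom, "pos": [1, 2, 1, 2]})
        bins = make_bins(idx, pb, min_total=8)
        assert all(len(set(pb.chrom[b["snps"]])) == 1 for b in bins)


class TestAggregate:
    def _one_bin_bundle(self, tiny_bundle):
        return tiny_bundle

    def test_orientation_formula(self, tiny_bundle):
        b = tiny_bundle.subset(spots=[0], snps=[0, 1])
        b.Y0[:, 0] = [3, 1]
        b.D0[:, 0] = [5, 4]
        pa = PhaseAssignment(
            h=np.array([HAP1, HAP2]), z=np.zeros(2, int), posterior_h1=np.ones(2)
        )
        bins = [{"chrom": "chr1", "snps": [0, 1], "start": 1, "end": 10}]
        bg = aggregate(b, pa, bins)
        assert bg.Y[0, 0] == 3 + (4 - 1)
        assert bg.D[0, 0] == 9

    def test_all_hap1_is_plain_sum(self, tiny_bundle):
        pa = PhaseAssignment(
            h=np.full(6, HAP1), z=np.zeros(6, int), posterior_h1=np.ones(6)
        )
        bins = [{"chrom": "chr1", "snps": list(range(6)), "start": 1, "end": 10}]
        bg = aggregate(tiny_bundle, pa, bins)
        np.testing.assert_array_equal(bg.Y[0], tiny_bundle.Y0.sum(axis=0))

    def test_all_hap2_is_complement(self, tiny_bundle):
        pa = PhaseAssignment(
            h=np.full(6, HAP2), z=np.zeros(6, int), posterior_h1=np.zeros(6)
        )
        bins = [{"chrom": "chr1", "snps": list(range(6)), "start": 1, "end": 10}]
        bg = aggregate(tiny_bundle, pa, bins)
        np.testing.assert_array_equal(
            bg.Y[0], (tiny_bundle.D0 - tiny_bundle.Y0).sum(axis=0)
        )

    def test_total_count_conserved(self, small_binned):
        bg, _, _, bundle = small_binned
        # aggregation conserves total allele counts per spot
        np.testing.assert_array_equal(bg.D.sum(axis=0), bundle.D0.sum(axis=0))

    def test_label_swap_leaves_baf_deviation_invariant(self, tiny_bundle):
        pa1 = PhaseAssignment(
            h=np.full(6, HAP1), z=np.zeros(6, int), posterior_h1=np.ones(6)
        )
        pa2 = PhaseAssignment(
            h=np.full(6, HAP2), z=np.zeros(6, int), posterior_h1=np.zeros(6)
        )
        bins = [{"chrom": "chr1", "snps": list(range(6)), "start": 1, "end": 10}]
        bg1 = aggregate(tiny_bundle, pa1, bins)
        bg2 = aggregate(tiny_bundle, pa2, bins)
        np.testing.assert_allclose(
            np.abs(0.5 - bg1.baf()), np.abs(0.5 - bg2.baf()), atol=1e-12
        )
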