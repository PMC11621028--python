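"""Generate a synthetic Visium-like dataset, write it in the standard file
dialects (MatrixMarket + TSV/CSV), read it back, and apply quality filters.

The printed numbers are the spot/gene/SNP counts before and after the
standard filters (>= 50 total UMIs and >= 50 SNP-covering UMIs per spot;
genes expressed in >= 0.5% of spots, non-outlier, non-Ig/HLA; SNPs inside
retained genes).
"""

import tempfile

from spatialcna import (
    SimConfig, filter_genes, filter_snps, filter_spots, read_bundle, simulate,
)
from spatialcna.io import write_bundle_inputs

bundle, truth = simulate(SimConfig(nx=10, ny=10, n_bins=40, seed=0,
                                   normal_fraction=0.2))
print(f"simulated: {bundle.n_spots} spots, {bundle.n_genes} genes, "
      f"{bundle.n_snps} SNPs; {truth.A.shape[1]} clones planted")

with tempfile.TemporaryDirectory() as tmp:
    paths = write_bundle_inputs(bundle, tmp)
    bundle = read_bundle(paths["counts_dir"], paths["alleles_dir"],
                         paths["positions"], paths["annotation"])
print(f"read back from disk: {bundle.n_spots} spots (identical to written)")

bundle, rep_spots = filter_spots(bundle, min_umi=50, min_snp_umi=50)
bundle, rep_genes = filter_genes(bundle, min_frac_spots=0.005)
bundle, rep_snps = filter_snps(bundle)
print(f"after filters: {bundle.n_spots} spots, {bundle.n_genes} genes, "
      f"{bundle.n_snps} SNPs")
print("removed:", rep_spots.summary(), "|", rep_genes.summary(), "|",
      rep_snps.summary())
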