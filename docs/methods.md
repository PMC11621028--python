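# Methods

This note documents the probabilistic models, the numerical choices, what
the synthetic data does and does not emulate, and the design decisions
taken where several reasonable options existed.

## Inputs and filtering

The pipeline consumes a gene × spot UMI matrix, two SNP × spot matrices
(counts supporting population-phased haplotype 1, and totals) at known
germline heterozygous SNPs, spot coordinates per slice, and a gene
annotation. Spots need ≥ 50 total UMIs **and** ≥ 50 SNP-covering UMIs
(both configurable). Genes are dropped when expressed (count > 0) in
fewer than 0.5% of spots, flagged by the outlier detector (default: local
outlier factor on log total expression, high side only), or annotated as
immunoglobulin/HLA. SNPs must fall inside a retained non-HLA gene
interval (closed intervals, same chromosome); intergenic SNPs are removed.
"Expressed" and the interval convention are our own conventions — the
simplest consistent readings. The 0.5% fraction is evaluated after spot
filtering. When gene-count and allele-count inputs disagree on barcodes,
the intersection is used (all three matrices are needed per spot).

## Phase-error correction

Population-based phasing is reliable locally but accumulates switch
errors with distance. Since every cell shares the same parental
haplotypes, allele counts are pooled over all spots and a single phase
vector is inferred for the sample. The HMM has joint hidden states
(h ∈ {hap1, hap2}, z ∈ {1..K_phase}); emissions are
BetaBinom(d, τp_z, τ(1−p_z)) for h = hap1 and the mirror for h = hap2;
transitions factorize with self-probabilities t (BAF cluster) and q
(phase). Parameters: K_phase = 5 with initial BAFs spread over
(0.05, 0.5] (the cluster count is our choice; imbalance levels in real
tumors occupy a handful of distinguishable BAF levels); τ initialized at
30; t = 1−1e−4, q = 1−1e−3 initially, both re-estimated. Chromosomes are
independent chains (transition reset with the start distribution).

Baum–Welch is implemented as generalized EM: t and q have closed-form
M-steps from expected transition counts; each p_z and τ is refit by
bounded scalar maximization of the expected complete-data log-likelihood
and accepted only when it improves — the observed-data log-likelihood is
therefore non-decreasing (asserted at 1e−8 relative tolerance in tests).
The phase/cluster assignment is the joint Viterbi path; ties break toward
the lower state index for determinism. Orientation is identifiable only
where the pooled BAF departs from 0.5; in balanced stretches (including
segments whose imbalance cancels across mirrored clones) the inferred
orientation is arbitrary, which downstream consumers must treat as a
per-segment gauge freedom.

## Binning and aggregation

Variable-length bins accumulate consecutive SNPs until the pooled total
allele count reaches a minimum (default 300; at the test depths this
yields the per-bin occupancy scale of a handful of SNPs and genes that
real Visium runs produce), with a possibly deficient final bin per
chromosome. Per spot, bin totals D sum member SNP totals; the B-haplotype
count Y adds Y⁰ for hap1-phased SNPs and D⁰ − Y⁰ for hap2-phased ones.
Transcripts are assigned by the gene's transcription start to the bin
whose SNP span contains it, else the nearest bin on the chromosome (each
gene must map to exactly one bin).

## Baseline and ASE masking

Normal spots are found either from tumor proportions (θ < 0.5) or by
k-means (k = 5) on per-bin BAF with empty bins imputed at 0.5, taking the
cluster whose center is nearest 0.5. The baseline λ is the normalized
pooled expression of normal spots. Bins whose pooled normal BAF deviates
from 0.5 (exact binomial test, Benjamini–Hochberg at α = 0.05) show
allele-specific expression unrelated to copy number and are masked from
inference. The clustering settings and the exact-binomial/BH test are our
substitutes for procedures that admit many implementations; the test is
the minimal one with controlled type-I error (verified on null
simulations).

## Clone and copy-number-state inference

States: K = 7 by default — three mirrored pairs sharing a read-depth
ratio μ_b with BAFs p_b and 1 − p_b, plus a balanced diploid anchor fixed
at (μ = 1, p = 0.5). The anchor resolves the scale degeneracy between μ
and the per-spot normalizer; mirrored pairs are what make mirrored
subclonal CNAs representable. Emissions per spot s, bin j, state k:
transcripts ~ NegBin(mean = T_s λ_j RDR_eff / C_s, dispersion φ), alleles
~ BetaBinom(D, τ·BAF_eff, τ(1−BAF_eff)), with the tumor-proportion mixture
RDR_eff = θμ + (1−θ) and BAF_eff = (θpμ + 0.5(1−θ))/(θμ + (1−θ)) — chosen
so the LOH limit reproduces the purity mixture formula exactly. C_s
normalizes state means to the observed spot total under the current
assignment.

The joint objective is the per-spot product likelihood plus the
genome-chain log-prior (shared self-transition, reset per chromosome) and
β × the Potts agreement over the neighbor graph (β = 2 per unit edge
weight by default — deliberately exposed, since an overly strong spatial
prior degrades inference). Optimization alternates: exact Viterbi state
paths per clone (emissions summed over the clone's spots); bounded 1-D
refits of each tied parameter and of τ, φ on the hard assignments, each
kept only if the joint objective does not decrease; a safeguarded update
of C_s; and iterated conditional modes for the labels (sweeps in spot
order, ties to the lowest clone index, restarted from each constant
labeling with the best objective kept — ICM is single-flip-local, and the
restarts escape coordinated-flip traps without breaking ascent). Every
step is non-decreasing, so the trace is monotone by construction, not
empirically. "Per-clone pseudobulk" here means summing per-spot emission
log-likelihoods over the clone (a product model) rather than summing raw
counts; this keeps the objective single-valued across the HMM and HMRF
blocks and makes ascent provable.

Labels initialize as spatially contiguous random partitions (seeded
region growing on the graph); 3 restarts with seeds derived from the user
seed are run and the best objective wins — restarts are the standard
remedy for coordinate-ascent local optima. With θ given, spots with
θ < 0.5 are pinned to a dedicated always-balanced normal clone; without
θ, that clone exists but spots move freely. Clones whose state-implied
(RDR, BAF) profiles differ on fewer than 5% of bins are merged and the
model briefly refit; initializing with more clones than expected
(default 5) and merging down selects the clone number.

## Tumor proportion

A BAF-only genome HMM (beta-binomial states, free BAFs, Baum–Welch under
a single-clone assumption) clusters bins; clusters with |p̂ − 0.5| ≥ 0.2
(default) are LOH. Per spot, counts over LOH bins are pooled with the
lost haplotype in the numerator and θ = (0.5 − f)/(0.5 + μf − f), clipped
to [0, 1]. μ comes from the observed/expected expression ratio over the
LOH bins when a baseline is available (support-weighted across regions),
else 1. Spots with < 10 LOH UMIs get θ imputed from their 6 nearest
spatial neighbors. Note the detection threshold interacts with
admixture: a region whose pooled deviation is shrunk below the threshold
by heavy normal admixture is genuinely undetectable at that setting.

## Integer copy numbers

Each state maps to argmin over {(a, b): 0 ≤ a, b ≤ 6, a+b ≥ 1} of
((a+b)/γ − μ)² + w·(b/(a+b) − p)², w = 1; the ploidy scale γ is selected
from {1.5, 2, 2.5, 3, 3.5, 4} by the state-occupancy-weighted total error
(near-triploid genomes are common). Homozygous deletion is excluded
(an RDR of 0 is not reliably measurable), and high-copy amplification
beyond 6 copies is out of range by design. If all states coincide, γ is
unidentifiable and defaults to 2 with a warning. Event labels are taken
relative to diploid (1,1): CNLOH (one allele absent, total 2), LOH (one
allele absent otherwise), del/amp by total, and a cross-clone mirrored
flag when two clones are imbalanced in opposite orientations.

## Phylogeography

LOH markers are maximal runs of bins (within a chromosome) over which the
clone-set having lost a given haplotype is constant; mirrored losses are
distinct characters. Filters: ≥ 3 bins and ≥ 100 SNP-covering UMIs in
each carrying clone. Under star homoplasy a marker may be gained on
several edges but never lost; the minimum-gain count for a carrier set S
on a tree equals the number of maximal subtrees contained in S, so each
topology is scored in closed form. All rooted binary topologies are
enumerated for ≤ 7 clones (root = LOH-free normal ancestor, all-zero
state); branch-and-bound (the restriction-score lower bound) covers 8–10;
beyond that a greedy agglomeration runs with a warning. Multiple
independent gains of one marker on disjoint edges are permitted — that is
what the star model allows. A clone leaf whose pendant edge gains nothing
while a sibling subtree does is contracted into its parent and reported
as the ancestor of its sisters; identical twins stay siblings.

Leaves sit at clone centroids (3-D when per-slice z offsets are given).
Ancestors maximize Σ_v log N(s_v | s_parent, w_e I) with leaves clamped —
a positive-definite linear system solved directly; the solution makes
each free node the precision-weighted (1/w) average of its tree
neighbors (residual < 1e−8 asserted). Zero-gain edges get variance
ε = 0.5 so the system stays definite. The root is estimated jointly, with
no anchor prior.

## Somatic SNV cascade

Pure predicates, so the surviving set is an intersection: not in the
germline panel; genic; zero variant reads in every normal spot (θ < 0.5)
and normal depth ≥ 15 (below which germline status cannot be excluded);
pooled tumor alt count ≥ 5 and pooled tumor VAF > 0.3. Pooled tumor
counts are the natural pseudobulk reading of "tumor VAF". "Any normal
spot with a variant read" is taken literally (> 0 alt reads in ≥ 1 normal
spot); no sequencing-error tolerance is applied.

## Synthetic data

The generator emulates the measurement model: hexagonal spot lattices
(square optional) across one or more slices, Voronoi clone territories
shared across slices, per-clone integer (A, B) profiles over bins (a
standard profile plants a truncal LOH, a mirrored (2,1)/(1,2) pair, a
CNLOH, a private amplification and a private mirrored LOH — the distinct
states fit the default 7-state capacity), Dirichlet per-gene baseline,
NB transcripts (φ = 0.05), per-SNP beta-binomial alleles (τ = 60),
per-spot admixture θ, and a first-order Markov flip process for phasing
switch errors (rate 0.02 — the block structure matches how switch errors
actually arise). Defaults give ~500 spots at 3,000 transcript / 300
allele UMIs per spot over 100 bins (8 SNPs, 5 genes each). Everything is
deterministic given the seed.

What it does **not** emulate: gene-level biological covariance and
cell-type expression programs, segmentation artifacts, spatial platform
noise (lattice deformation, bleed-over), histology, or reference-panel
phasing itself. Passing recovery tests therefore demonstrates
correctness of the inference under the model's own assumptions, not
robustness to expression confounders that real tissue adds.

## Problem sizes and numerics

Recovery tests run at ~500 spots × ~380 post-binning bins × 7 states,
monotonicity checks at 36 spots × 16 bins across 20 seeds — sizes chosen
so the full suite completes in a few minutes while keeping the recovery
regime representative. All HMM arithmetic is in log space; beta-binomial
and negative-binomial pmfs come from scipy.stats; scalar refits use
bounded Brent (minimize_scalar) with explicit accept-only-if-better
safeguards; Viterbi and ICM ties break toward lower indices; seeds thread
from a single user seed through numpy Generators.

## Known limitations

Orientation of mirrored segments whose pooled BAF is exactly balanced is
a gauge freedom (resolved only relative to the inferred phase). Tumor
proportion is unavailable without detectable LOH. The HMRF optimum is
local (mitigated, not eliminated, by restarts). Integer copies above 6
and homozygous deletions are not represented. The clone-count heuristic
(over-initialize then merge) can under-split clones distinguished only by
very short segments at low depth.
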