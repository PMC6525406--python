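# Methods

## Scope and data model

radpop analyzes multi-population panels of biallelic SNPs held as a
`GenotypeMatrix`: sites × samples alt-allele dosages in {0, 1, 2, missing}
with per-genotype read depth and a sample→population map. Inputs are
VCFv4.x (GT required, DP optional; multiallelic and non-SNP records are
skipped and counted) plus a two-column population map. All coordinates are
1-based; only biallelic SNPs are retained.

## Synthetic-data generator

The generator is the package's reference experiment: it plants a known
history and lets every downstream statistic be checked against truth.

*Frequencies.* Ancestral frequencies are Uniform(0.05, 0.95) per site
(avoiding near-fixed sites keeps SNP-ascertainment loss small; discarded
monomorphic sites are counted and reported). Along each branch with drift
parameter c ∈ (0, 1), the child frequency is beta-distributed with mean p
and variance c·p(1−p) (the Balding–Nichols moment-matched form, support
[0, 1], asymptotically compatible with the Gaussian-drift covariance model;
c is clipped to [10⁻⁶, 0.999]). Admixture is a single pulse at tip time:
p_target ← (1−α)p_target + αp_source, applied in event order. Continuous
migration is out of scope.

*Genotypes.* Inbreeding-adjusted Hardy–Weinberg draws:
P(het) = 2p(1−p)(1−F), P(hom alt) = p² + Fp(1−p). Depth is
Poisson(depth_mean, default 16 reads); each genotype is missing
independently with probability miss_rate. Sites monomorphic across all
sampled calls are discarded and counted. Sites occupy one synthetic
chromosome at 1 kb spacing — enough structure for SNP-count jackknife
blocks; there is no recombination map or linkage beyond block adjacency,
no sequencing-error model, and no coalescent gene-tree variance. Test
outcomes therefore demonstrate correctness of the estimators under the
drift model, not robustness to genotyping error or linked selection.

*Reads.* The FASTQ generator plants exactly one QC class per read (clean,
high-N, low-quality, adapter-bearing) and audits each read against all
three filter rules at construction, so the truth table is exact by design.

*Seeding.* All randomness flows from one integer seed; each stage draws
from `default_rng(SeedSequence([seed, stage]))` (0 = frequencies,
1 = genotypes, 2 = reads), making stages independently reproducible and
outputs byte-identical across runs.

*Default study shape.* Simulation-based tests use 5 populations of 8
diploids and 5,000–20,000 SNPs. Branch drift values of c ≈ 0.02–0.08 with a
c ≈ 0.2 outgroup correspond to populations separated by roughly 1–10 Myr at
moderate effective size; the weaker setting (c = 0.02 internal branches) is
used for the admixture experiments, where subtle drift keeps pulse
detection non-trivial, and the moderate setting for topology recovery and
dating, where the spec of the experiment is a well-resolved radiation.

## Read QC

Rule boundaries follow the stated definitions exactly: the N rule is
inclusive (≥10%), the quality rule strict (>50% of bases below phred 5),
the adapter rule strict (>10 nt). Adapter matching is ungapped: over every
alignment diagonal of read against adapter, the longest window whose
mismatch count is ≤ floor(0.10·L) is found by cumulative-sum scanning; the
mismatch budget uses integer truncation (the conservative reading of "≤10%
mismatches"). Reads are removed whole, never trimmed; pairs are filtered
independently; phred encoding is fixed at +33. Rule attribution is
first-match in the order N → quality → adapter.

## Site filtering

Depth masking (genotype DP < dp_min → missing) precedes the site rules, in
line with common Stacks/VCF practice. The missingness threshold of 0.7 is
interpreted as a minimum per-site call rate (Stacks -r semantics); the
alternative reading — maximum missingness — is available by setting the
threshold accordingly.
MAF is pooled across all samples, matching a single global filtering pass
before per-population extraction. The duplicated-region proxy — site
heterozygosity > 0.75 across all samples, or mean site depth > 2.5× the
genome-wide mean — uses the two standard paralog signatures; both
thresholds are configurable. Filtering is idempotent and order-stable.

## Diversity

π per site is 2k(n−k)/(n(n−1)) over called allele copies — identical to
the mean pairwise difference among copies — averaged over sites with ≥2
copies. Because the matrix holds variable sites only, π is reported per
retained SNP; a `callable_length` parameter rescales to per-bp values when
the callable genome size is known (real-data π magnitudes of ~0.01 imply
such a denominator). He uses Nei's 1978 small-sample correction
(2n/(2n−1)); the plain 1 − Σp² form is available by flag. Sites with fewer
than two called individuals are excluded from He/Ho means.

## Phylogeny

*Distances.* Nei standard genetic distance in its biallelic form,
D = −ln(J_ab / √(J_aa·J_bb)), over jointly called sites. By default the
within-population identities use the unbiased estimator (nJ−1)/(n−1): raw
p² sums are inflated by sampling variance (E[p̂²] = p² + p(1−p)/n), which
otherwise adds a constant to every between-population distance and badly
biases downstream dating of young nodes. The plain estimator remains
available (`unbiased=False`). Infinite distances are capped at 2× the
largest finite entry; negative small-sample estimates are clamped to 0.

*Tree building.* Textbook NJ (Q-criterion) with negative branch lengths
clamped to 0, rooted on the outgroup's branch midpoint (or the first taxon
when no outgroup is given — likelihoods under the reversible model do not
depend on root placement). UPGMA uses average-linkage clustering and is
ultrametric by construction.

*Likelihood.* The substitution model is the two-state symmetric chain:
P(change | t) = (1 − e^(−2t))/2, stationary (½, ½) — a deliberate,
documented substitute for nucleotide GTR+Γ, appropriate because SNP
matrices carry two states and no constant sites; rate heterogeneity is
omitted. Dosage 0 maps to state {ref}, 2 to {alt}, and 1 or missing to
{ref, alt} (a heterozygote carries both alleles). Site patterns are
compressed to unique columns before pruning, and partials are rescaled
per node to avoid underflow. An optional ascertainment correction divides
each site likelihood by (1 − L(all-ref) − L(all-alt)), conditioning on
variability. Population-level trees use a consensus matrix (per-population
frequency rounded to the nearest of 0/1/2 copies at thresholds 0.25/0.75).

*Search.* Rounds alternate full branch-length optimization (bounded scalar
search per branch on [10⁻⁹, 10], tolerance 10⁻⁶, passes repeated to
convergence) with NNI sweeps (both rearrangements per internal edge,
re-optimized, accepted above a 10⁻⁶ log-likelihood gain), stopping at a
sweep with no improvement or 20 rounds. The likelihood trace is
non-decreasing by construction. At very weak drift (c ≈ 0.02) the
consensus two-state likelihood can genuinely prefer a wrong topology in a
minority of replicates — a model-informativeness limit, not a search
failure; distance NJ is more robust there and is the bootstrap default.

*Bootstrap.* SNP columns are resampled with replacement; each replicate is
rebuilt (fast: NJ on Nei distances; full: the NNI search) and internal
bipartition frequencies become percent supports. The default is 100
replicates, configurable (1000 matches common practice at ~10× the cost).

*Dating.* UPGMA depth is converted to age by a strict clock:
scale = calibration midpoint / depth of the calibration pair's MRCA; the
anchored node's age is exact by construction and tips sit at age 0. This
replaces Bayesian relaxed-clock dating; it assumes clock-like drift and a
tree-like history — admixture pulses shorten distances between the mixed
populations and locally distort ages (demonstrated in example 04).

## Introgression

The frequency-weighted D estimator (numerator (w′−x′)(y′−z′), denominator
(w′+x′−2w′x′)(y′+z′−2y′z′)) is the standard population-frequency form
consistent with the verbal BABA/ABBA role definitions: Z is the outgroup,
Y the reference lineage, and positive D (BABA) means excess derived-allele
sharing between W and Y. Sites with any missing frequency are dropped
per-quartet (complete case). Standard errors come from a weighted
delete-one block jackknife over contiguous 500-SNP blocks (weights: block
denominator mass, Busing-style variance); |Z| > 2 is the significance
rule. On no-admixture simulations the empirical null is well calibrated
(Z s.d. ≈ 0.98; |Z| > 2 in ~5–7% of replicates). The quartet scan
evaluates all (W, X, Y) triples with W < X lexicographically against a
fixed outgroup, sorted by |Z|.

## Migration graphs

The observed statistic is the centered covariance across sites of
population allele frequencies. Binomial sampling variance — estimated
unbiasedly per site as p̂(1−p̂)/(n−1) and averaged — is removed in its
*centered* form H·diag(S)·H (H the centering operator): centering mixes
each population's sampling noise into every matrix entry, so subtracting
only the diagonal would leave a bias of order S/k everywhere, large enough
at small sample sizes to swamp genuine admixture residuals. The tree model
predicts uncentered covariance as shared root-to-MRCA drift path length;
branch lengths are fitted by NNLS to the doubly centered prediction.
Because centering makes the two root-adjacent branch columns collinear,
only their sum is identifiable — fitted individual values of those two
branches are reported but arbitrary within that constraint.

A migration edge (s → t, weight α) replaces tip t's path indicator with
(1−α)·path(t) + α·path(s), the linear (first-order) mixture of expected
drift paths. The greedy search scans all ordered tip pairs × an α grid
(0.05…0.50 by 0.05), refits branch lengths for each candidate, and accepts
the best edge while its relative SSE reduction is ≥ 0.05 (one inbound
pulse per target). The SSE trace is non-increasing by construction. The
base topology comes from NJ on the covariance-implied distances
d_ab = cov_aa + cov_bb − 2·cov_ab; topology search under the covariance
objective, migration from internal branches, and the full Gaussian
composite likelihood are out of scope. Known limitation: on noisy tree-only
data the relative-SSE rule can accept spurious low-weight edges (it asks
whether an edge explains residual noise, not whether the improvement
exceeds sampling error); with an exact tree covariance it accepts none.

## Pipeline

Stages run in a fixed order (QC → matrix → diversity → phylogeny →
D-statistics → migration); configuration is validated before any stage
runs, every enabled stage writes stable file names under one output
directory, and the run report echoes the full configuration, so a report
suffices to reproduce a run. With a fixed seed all outputs are
byte-identical across runs.

## Numerical conventions

Missing dosage/depth is the sentinel −1 internally and "./." in VCF.
Likelihood branch bounds [10⁻⁹, 10]; NNI acceptance 10⁻⁶; NNLS is exact
for these problem sizes; jackknife requires ≥2 blocks with positive
denominator; degenerate cases (empty matrix, zero-denominator D, unsplit
calibration pair) raise informative errors rather than returning silent
defaults.
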