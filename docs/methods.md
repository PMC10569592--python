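# Methods

This note records the models behind each module, the defaults and why they
were chosen, what the synthetic cohorts do and do not emulate, and the
numerical decisions a maintainer would want written down.

## Data model and coordinates

Genotypes are alternate-allele dosages per biallelic site per sample, with
ploidy resolved from metadata: males are haploid on the X, and low-quality
genomes are *pseudo-haploid* (one confidently called allele per site)
everywhere — so a nine-genome cohort of 6 females / 3 males with 4
low-quality females contributes 14 autosomal and 11 X alleles. VCF input
and output are 1-based; every internal interval (windows, masks, BED) is
half-open 0-based. Non-biallelic sites are excluded at load time with a
logged count. A total allele count of at least 4 gates site use in all
statistics; singletons are additionally excluded from demographic
inference, where damage-driven artifacts matter most.

Windows are defined by reference-panel SNP content (25,000 SNPs for IBD
detection, 250 for the selection scan, mirroring the density-scaled
windows of modern *D. melanogaster* panels). Window boundaries fall at the
midpoint between the last reference SNP of one window and the first of the
next, so windows tile each chromosome without gaps; a partial terminal
window is retained and flagged rather than silently merged or dropped.

## Synthetic cohorts

The generator produces the cohort conditions every downstream stage is
tested under: two historical cohorts (defaults 9 and 14 genomes, mixed
sex, 4 and 2 pseudo-haploid low-quality females) and a modern pool-seq
cohort of 120 male flies, with eras linked by Wright–Fisher binomial drift
at a configured diploid Ne (default 3,000; haploid size 2Ne) over
(calendar years) × 15 generations. Founder frequencies follow a symmetric
Beta(0.4, 0.4) — a folded-SFS-shaped choice that keeps singleton logic
exercised without committing to a specific demographic history.

Relatedness and inbreeding are planted by copying haplotype segments in
blocks of a configurable site count (full sibs copy one haplotype per
block with probability 1/2, parent–offspring with probability 1,
second-order relatives 1/4), which matches the window scale at which the
detector operates; no recombination map is simulated. Sweeps are
deterministic logistic frequency paths between eras, applied to a block of
consecutive sites (default 10 in the pipeline) to stand in for the
hitchhiking footprint a hard sweep leaves across a window — exact truth
for power tests, not a model of selection dynamics. Sweep overrides are
applied era by era, so cohorts sampled after the sweep inherit and drift
from the swept frequency. Damage is injected as
sample-private derived alleles at panel-monomorphic sites, with the A/T
fraction of injected errors set by quality tier (defaults 0.55 for
high-quality, emulating the modern singleton baseline, and 0.70 for
low-quality, within the 60–74% range typical of degraded genomes).

What the generator does *not* emulate: linked sites (all sites are
independent), sequencing-read error processes other than the singleton
channel, structural variation, X-specific effective sizes, or migration.
Tests passing on these cohorts therefore validate the estimators'
bookkeeping and statistical behavior under drift, not robustness to
linkage or alignment artifacts in real data.

## IBD detection

Pairwise per-site distance is the mean mismatch over all cross-pairs of
alleles (4 comparisons for diploid–diploid, 2 haploid–diploid, 1
haploid–haploid), i.e. pᵢ + pⱼ − 2pᵢpⱼ in per-sample frequency terms,
averaged over shared non-missing sites per window. Note that two identical
unphased heterozygotes have distance 1/2 under this definition — identity
of genotype is not identity of haplotype.

Each genome's background distance dᵢ (median vs. an unrelated outgroup
panel, per window) is divided by the median of all focal-vs-outgroup
distances to give the scaling factor mᵢ, and D′(i,j) = d(i,j)·mᵢ·mⱼ. With
one haplotype IBD between diploids, a quarter of allele comparisons match,
so E[D′] = (3/4)·D; the call threshold is the midpoint (7/8)·D. The same
midpoint construction gives (1/2)·D for haploid–haploid (expected IBD
distance 0) and (3/4)·D for haploid–diploid (expected (1/2)·D).

The baseline D ("median pairwise distance among individuals with no
obvious IBD") is circular, so it is iterated: compute D from all pairs,
flag, recompute excluding flagged pairs, repeat to convergence (at most 5
rounds; convergence is typically immediate). Windows left with fewer than
3 non-IBD pairs fall back to the chromosome-arm median. D is computed on
the rescaled (D′) scale so the threshold comparison is scale-consistent.

Inbreeding uses the same windows: a diploid whose window heterozygosity is
below π/2 is flagged, with π taken as that window's non-IBD median
pairwise distance (the same quantity as D, keeping the two detectors
internally consistent), and one randomly chosen (seeded) allele masked.

Masking covers the called window plus the proximate halves of both
flanking windows — deliberately conservative against IBD tracts that
straddle boundaries. When one pair member must be masked: low quality
loses to high quality; between equals, the member with more windows
already masked is masked again (concentrating data loss in fewer genomes);
remaining ties break lexicographically. Half-window flanks are applied to
inbreeding blocks as well.

Window size matters: the margin between the IBD expectation and the
threshold is D/8, and the window mean distance has standard error roughly
√(Var_site/S) for S SNPs per window. At realistic per-site diversity the
25,000-SNP production window puts the margin at many standard errors; the
test fixtures use 2,000–3,000-SNP windows, which is the smallest scale at
which the <1%-false-positive property still holds comfortably.

## Pool-seq effective alleles

Stirling numbers of the second kind are computed by the triangular
recurrence S(n,k) = k·S(n−1,k) + S(n−1,k−1) in log space (all terms
nonnegative, so logaddexp suffices); direct computation overflows doubles
near n ≈ 220. The lineage distribution is evaluated without renormalizing
— its total serves as an internal consistency check (within 1e-9) — and
the expectation agrees with the occupancy closed form n_c(1−(1−1/n_c)^{n_r})
to better than 1e-9 relative error across the relevant depth range. Sites
are called polymorphic at ≥5 minor-allele reads (relaxed to 1 for the
inversion assay, which must see rare inversion-linked alleles).
Downsampling to the effective count is deterministic — frequency ×
rounded expectation, apportioned by largest remainder — matching a
frequency-rescaling rather than a resampling interpretation.

## Diversity and differentiation

π uses the unbiased per-site form 2p̂q̂·n/(n−1) (the correction is
material at the 4-allele downsampled depth used for cross-cohort
comparisons). FST is Hudson's two-population estimator with window
aggregation as a ratio of summed numerators over summed denominators,
isolated in one function so an alternative estimator can be swapped in;
negative per-window estimates are floored at 0 before the −log(1−FST)
transform (they are sampling noise, and the transform requires FST < 1;
windows with FST = 1 are excluded). The 4-allele hypergeometric
downsampling is unbiased for π, which the suite verifies over seeds.

PCA operates on the haplotype × site minor-allele matrix restricted to
complete polymorphic sites, taking all eigenvectors of the haplotype
correlation matrix (35 components for 5 haplotypes × 7 populations);
component signs are fixed by making each component's largest-magnitude
loading positive.

Inversion frequency is the median over marker-allele frequencies: when
only a few of a panel's markers are present at low frequency, the
majority-absent pattern indicates the inversion itself is absent, and the
median reports 0 where a mean would report a spurious small positive
frequency. Karyotype contrasts use the two-tailed Fisher exact test.

## Drift-only Ne estimation

The initial population frequency at each site is a discrete posterior on
512 equally spaced interior grid frequencies, combining a binomial
likelihood with a mutation–drift equilibrium prior ∝ 1/f + 1/(1−f) (both
allele labelings folded; the θ constant cancels). A uniform prior is
provided as an option; the two give near-identical posteriors for
balanced observed counts and posterior means within ~0.05 everywhere at
the historical sample size, though their total variation distance is
substantial for skewed counts — the prior genuinely matters in the tails.

Forward simulation draws each generation's frequency as a binomial of the
*haploid* candidate size N* (reported alongside the diploid equivalent
N*/2), treating sites as independent (linkage equilibrium). Absorbed
trajectories (f ∈ {0,1}) are dropped from the update loop — an exact
optimization, since binomial sampling fixes them forever. Terminal
sampling mirrors the data: n alleles for individually sequenced cohorts
(14 autosomal / 9 X for the historical design), or a two-stage draw of
240 pool alleles followed by n_eff reads for pool-seq (medians 145
autosomal / 70 X), which adds the extra sampling variance pool data
carries. The observed mean |Δp| is computed over sites segregating at t0
(a toggle allows either-timepoint segregation), polarized to the t0 minor
allele.

The grid search runs 1,000..20,000 in steps of 1,000 (1,000 replicates per
point by default) and refines ±500 in steps of 100 around the coarse
optimum; simulated |Δp| is strictly decreasing in N*, which is what makes
the grid-argmin meaningful. Because Monte-Carlo noise in the simulated
mean is far below the sampling noise of the observed data at these sample
sizes, validation experiments use 150–300 replicates and a few hundred
sites; recovery of a generating N* = 3,000 over 1,860 generations is
unbiased with seed-to-seed scatter of roughly ±20% at 200–250 sites,
which sets the recommended minimum site count. Recovery experiments draw
true initial frequencies from the estimator's own equilibrium prior; a
mismatched generative SFS (e.g. Beta(0.4, 0.4)) shifts fitted N*
noticeably, which is worth remembering when interpreting fits to real
data whose SFS is unknown.

The expected-π diagnostic integrates the pairwise coalescence survival
function across piecewise-constant epochs (rate 1/(2N) per generation for
diploid size N): E[T₂] = Σ_k S_k(1−e^{−λ_k d_k})/λ_k, and π = 2μE[T₂]
with μ = 5.21×10⁻¹⁰ per site per generation by default — reducing to
4Nμ for a single epoch. A Monte-Carlo sampler of the same history serves
as an independent oracle. Recombination parameters are recorded in
configuration for provenance but do not enter the expectation. The
diagnostic's role: if data generated with migration are fitted
drift-only, the fitted N* underestimates the truth and its expected π
falls short of observed π — the signature that a drift-only history is
inadequate.

## PBE scan

Window FST values become branch lengths d = −log(1−FST); PBS =
(d_f1 + d_f2 − d_12)/2 estimates the focal branch, and PBE = PBS −
T·median(PBS)/median(T) (T = d_12) subtracts the locus-specific
expectation scaled from the non-focal pair, so loci long on every branch
do not score. These are the standard published forms; the verbal
definition leaves the scaling constant open, and both functions are
isolated for substitution. Medians are genome-wide across analyzed
windows (a per-arm option exists). Outliers are the top 1% by window PBE
with ties at the threshold included; outlier windows separated by ≤2
non-outliers merge into regions ranked by maximal window PBE. SNP-level
PBE inside regions reuses the *window-level* median ratio — SNP-level
medians over outlier regions only would be biased high, deflating SNP
PBE. Window FST uses full post-masking counts by default with a
downsampling option, since the window statistic is a ratio of summed
components and robust to modest sample-size variation.

## Enrichment

Each permutation relocates every outlier region to a uniform random start
on a length-weighted random chromosome, preserving region length; a
term's raw p is the share of permutations with at least as many
region–term overlaps as observed. Relocated regions may overlap each
other (a rejection option disables this). p = 0 prints as "< 1/n_perm"
while the raw proportion stays in the data column, and no multiple-testing
correction is applied — these are screening statistics. Because the
statistic is discrete, raw p-values are conservative rather than uniform
under the null; the output includes the strict-exceedance proportion so
randomized-p calibration checks are possible, and the suite verifies both
validity and randomized-p uniformity. Region relocation is what keeps
physically clustered same-term genes from inflating significance: the
cluster is hit as one unit, where independent gene resampling would count
each member as separate evidence.

## Pipeline

Stages run in a fixed order with per-stage seeds derived from one global
seed by hashing the stage name — toggling stages on or off does not
change the randomness any other stage sees. Each stage consumes only
declared upstream outputs and fails by naming the missing stage. The
driver scripts under `analysis/` use a moderate Monte-Carlo profile
(6,000 sites per chromosome, 300 replicates per grid point, 5,000
permutations) so each completes in minutes; production-scale parameters
are the library defaults. The configuration is serialized into every
output directory, and identical seeds give byte-identical tables.

## Known limitations

Unlinked-site simulation means no LD-based validation is possible;
window-level truths are planted, not emergent. The IBD detector's
specificity degrades below ~2,000 SNPs per window. The drift-only Ne
fit's scatter grows quickly below ~200 usable sites. The X chromosome
drifts at the autosomal haploid size in the generator. Inversion
karyotype counts for the Fisher contrast must be supplied by the caller
(the frequency estimator does not infer individual karyotypes). The
enrichment null relocates regions anywhere in the genome; confining
permutations to the analyzed (non-excluded) fraction is available as an
option but not the default.
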