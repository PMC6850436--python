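# Methods

## Model

For two non-inbred diploid individuals from one homogeneous population, the
probability of observing the genotype pair (g₁, g₂) at a diallelic site with
allele frequency p decomposes over the pair's IBD state:

    P(g₁, g₂ | p) = k₀·M₀(p) + k₁·M₁(p) + k₂·M₂(p)

where (k₀, k₁, k₂) are the genome fractions sharing 0/1/2 alleles identical
by descent and the conditional matrices are

* M₀(p): independence — the outer product of Hardy–Weinberg margins
  (q², 2pq, p²), q = 1 − p;
* M₁(p): one shared allele S ~ Bernoulli(p) plus one free allele per
  individual, giving cells (0,0)=q³, (0,1)=(1,0)=pq², (1,1)=pq,
  (1,2)=(2,1)=p²q, (2,2)=p³ and zero for opposing homozygotes;
* M₂(p): identical genotypes, Hardy–Weinberg on the diagonal.

All statistics (R0, R1, KING-robust kinship, IBS0/IBS2, Lee) are ratios of
sums of cells of the genome-wide tally of these pairs. Two structural facts
drive the whole method:

1. **Invariances.** Every statistic is invariant under allele relabeling
   (180° rotation of the matrix) and individual swap (transposition), so
   no allele orientation or sample ordering matters. The implementation
   keeps these invariances bit-exact by using exactly-rounded (`fsum`)
   summation for the multi-cell aggregates.
2. **Spectrum linearity.** The expected cell mass under an allele-frequency
   spectrum w is linear in w, so each statistic's expectation is a
   linear-fractional function of w. Its extremes over *all* spectra are
   therefore attained at point-mass spectra, and the attainable joint
   region in the (R1, R0) or (R1, kinship) plane is traced by single
   frequencies plus two-point mixtures. `expectation_range` exploits this:
   per-statistic ranges are exact on the grid; joint regions are sampled
   over the grid (default 512 folded frequencies on [0.001, 0.5]) and all
   two-point mixtures of a 4-fold strided sub-grid with 21 mixture
   weights. A useful corollary the test suite checks: the *expected*
   KING-robust kinship equals θ = k₁/4 + k₂/2 at every single frequency,
   so its theoretical range is a point for every relationship.

Degenerate inputs: any statistic whose denominator is empty returns NaN
with a `RelatednessWarning` rather than raising, so batch analyses of many
pairs proceed; classification of NaN statistics returns "unclassifiable".

## Estimation from genotype likelihoods

With sequencing reads instead of genotypes, the per-site category is
latent. Both estimators maximise the mixture likelihood
∏ₛ Σ_c π_c · GL₁(g₁(c)) · GL₂(g₂(c)) by plain EM from a uniform start:

* **SFS mode** (3-genotype likelihoods, designated allele per site):
  9 components = the A–I cells directly.
* **IBS mode** (10-genotype likelihoods, no allele information):
  100 components; the estimate is collapsed onto A–I by allele-union,
  discarding pairs with more than two distinct alleles (their estimated
  mass is reported). Without an allele orientation only the four
  relabel-invariant aggregates are identifiable, so collapsed mass is
  spread evenly within its aggregate — immaterial to every statistic.

Likelihood vectors are scale-free; each site is normalised to max 1 and
accumulation is in log space. **Stopping rule:** EM stops when the largest
proportion change falls below 1e-8 (default; max 2000 iterations). A
log-likelihood-gain rule was rejected: components whose true proportion is
zero (e.g. opposing homozygotes for a parent–offspring pair) decay
geometrically and produce negligible likelihood gains long before reaching
the boundary, which leaves R0 visibly inflated at 4x depth; a gain
threshold is also scale-dependent in the number of sites.

**Chunking.** `chunked_estimate` runs the EM per chromosome and pools the
expected counts — the memory-bounded mode for genome-scale data, and the
source of per-chromosome counts for jackknifing. Small chunks carry a real
cost: the per-chunk ML places a small spurious opposing-homozygote mass
(a boundary estimate cannot be negative, so chunk-level noise cannot cancel),
inflating IBS0; a warning is emitted for chunks under 5000 sites. For data
that fit in memory, `em_jackknife_stats` is preferred: one joint EM over
all sites, with leave-one-chromosome-out SEs computed by re-running the EM
on each reduced data set warm-started from the all-data solution (warm
starts are floored at 1e-12 because a multiplicative update cannot revive
an exactly-zero proportion).

## Uncertainty

Sites are treated as independent in estimation, but LD and shared IBD
segments correlate them, so per-site resampling understates uncertainty.
SEs therefore come from a delete-one-chromosome weighted jackknife
(delete-m_j form): with block site counts m_j (total n, g blocks,
h_j = n/m_j),

    θ̂_J = g·θ̂ − Σ_j (1 − m_j/n)·θ̂₍₋ⱼ₎
    Var  = (1/g) Σ_j (h_j·θ̂ − (h_j−1)·θ̂₍₋ⱼ₎ − θ̂_J)² / (h_j − 1)

Each leave-one-out value θ̂₍₋ⱼ₎ is the statistic recomputed from the pooled
counts of the remaining blocks (or a re-run EM), never an average of
per-block statistics. With equal blocks this reduces exactly to the
classical delete-one jackknife (tested). Undefined leave-one-out values
(a removal emptying a denominator) are dropped with a warning. Intervals
are reported as ±2 SE throughout. For inputs without contig labels a
contiguous-site blocking (default 22 blocks) is provided; it cannot respect
the true correlation structure and is documented as weaker.

## Classification

Two schemes, deliberately independent:

* **(R1, R0) nearest reference point** (Euclidean). Reference points ship
  frozen from the package simulator — constant-size-population spectrum,
  10⁶ sites per relationship, seeds 2019–2023 — and are regenerable with
  `make_reference_points` / `pairkin make-refs`; a test asserts the frozen
  values regenerate exactly. Exact distance ties break toward the less
  related category (the conservative choice; the tie-break is a package
  convention, not derived).
* **Kinship bands** at 2^(−3/2), 2^(−5/2), 2^(−7/2), 2^(−9/2) (the
  standard powers-of-two criteria) plus a 2^(−13/2) floor separating
  "unknown/distantly related" (UK-DR) from unrelated; the 1st-degree band
  splits into PO vs FS on R0 < 0.02, since opposing homozygotes are
  essentially impossible for PO but not FS.

## The synthetic-data generator

What it emulates: per site, an allele frequency drawn from a configurable
spectrum; four founder haplotypes Bernoulli(p); an IBD state drawn
independently per site from (k₀, k₁, k₂); genotypes assembled from founder
alleles by state (individual 1 = haplotypes 1+2; individual 2 = 3+4, 1+3 or
1+2 for states 0/1/2). Optional layers: MAF ascertainment (site kept when
the minor allele count in a 40-chromosome panel — the 4 founders plus 36
extra population draws — exceeds 2, i.e. MAF > 5%; implemented by rejection
with a 200-round cap that errors on rules incompatible with the spectrum);
Poisson(λ)-depth reads (default λ = 4, matching low-depth resequencing)
with base error ε = 0.01 (≈ Q20) converted to GATK-model genotype
likelihoods, GL(g) = ∏_reads [½P(b|a₁) + ½P(b|a₂)], P(b|a) = 1−ε or ε/3;
Balding–Nichols cross-population pairs (population frequencies
Beta(p(1−F)/F, q(1−F)/F)); and RADseq-like subsetting to random
non-overlapping 200-bp windows allocated across chromosomes by length.
Sites get contiguous chromosome labels (default 22) and strictly
increasing positions on a 50-Mb default genome span (≈0.02 sites/bp at the
default 10⁶ sites), purely so blocking and window subsetting have
coordinates to act on.

Built-in spectra: `neutral_constant` — the expected SFS of a constant-size
neutral population on 40 chromosomes, weight ∝ 1/j; "expansion" and
"decline" are tilts of it (weight ∝ j^−1.5 and j^−0.5), qualitative
stand-ins for recent 10-fold growth/shrinkage (more/fewer rare variants),
not exact coalescent expectations. Founder alleles are *not* conditioned on
being polymorphic within the pair: a site monomorphic among the founders
lands in cell A or I exactly as in real genotype data. This choice only
moves mass between the ratio-statistic-irrelevant cells A/I, and it is what
makes the ascertainment sensitivity of IBS0 (and the robustness of
R0/R1/kinship) visible at realistic magnitude.

What it does **not** emulate, hence what passing tests do not show about
real data: linkage disequilibrium and the biological (recombination-driven)
variance of IBD sharing — IBD states are independent across sites, so
between-chromosome variation in simulated data is pure sampling noise and
jackknife calibration on simulations says nothing about LD handling on real
genomes; mapping and alignment artefacts; base-quality variation
(a single fixed ε); inbreeding and admixture.

## Problem sizes and numerical choices

Simulation sizes are chosen for Monte-Carlo precision: 10⁶ sites for the
parent–offspring anchor and the low-depth recovery runs; 4×10⁶ for the
unrelated-pair null checks (the jackknife SE of R0 is ≈0.004 at 10⁶ sites,
so 4×10⁶ brings it to ≈0.0015, comfortably inside the ±0.005 check);
200 replicates of 110 000 sites (22 equal blocks) for interval calibration;
window subsets of 50 000 and 10 000 windows (10 M and 2 M candidate bp of
the 50-Mb genome) for the reduced-representation stability check. Unit
tests run smaller versions of the same constructions. The MAF-ascertainment
robustness comparison is performed on the constant-demography spectrum,
where the measured relative IBS0 shift is ≈56% while R0 and kinship move by
less than 0.005.

## Known limitations

* The IBS (10-genotype) EM materialises an n×100 likelihood matrix; at
  10⁶ sites that is ~0.8 GB, so genome-scale IBS runs should use
  `chunked_estimate` (accepting the small-chunk IBS0 caveat above).
* Reference points and kinship bands target the five close-relationship
  categories; relationships beyond first cousins are collectively UK-DR/UR,
  and no pedigree reconstruction is attempted.
* The samtools-style correlated-error likelihood model is not implemented;
  likelihood input from other tools is accepted as-is.
* Cross-population pairs are detected (R0 ≫ 0.5), not corrected for.
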