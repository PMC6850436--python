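# pairkin

Allele-frequency-free inference of close familial relationships between
pairs of individuals, from genotypes **or** from low-depth sequencing data
via genotype likelihoods.

## Who this is for

Studies of non-model organisms, ancient samples or small cohorts often have
no reliable population allele frequencies, no good reference assembly (so no
usable positions of variants relative to each other), and sequencing too
shallow (~4x) to call genotypes. Most relatedness estimators need at least
one of those. `pairkin` needs none: every statistic it computes depends only
on the two target individuals.

## The method

At a diallelic site, a pair of diploid individuals shows one of nine
genotype combinations. Writing the genome-wide counts of those combinations
as a 3×3 matrix

|        | g₂=0 | g₂=1 | g₂=2 |
|--------|------|------|------|
| **g₁=0** | A | B | C |
| **g₁=1** | D | E | F |
| **g₁=2** | G | H | I |

three ratio statistics summarise the pair's relatedness:

* **R0 = (C+G) / E** — opposing homozygotes over double heterozygotes.
  Essentially 0 for parent–offspring pairs, 0.5 for unrelated pairs from one
  homogeneous population (for *any* allele-frequency spectrum), above 0.5
  when the two genomes come from different populations.
* **R1 = E / (B+C+D+F+G+H)** — double heterozygotes over all sites where
  the two genotypes differ.
* **KING-robust kinship = (E − 2(C+G)) / (B+D+F+H+2E)** — approximates the
  kinship coefficient θ = k₁/4 + k₂/2 for non-inbred same-population pairs,
  where (k₀,k₁,k₂) are the genome fractions sharing 0/1/2 alleles IBD.

The joint expectation regions of (R1, R0) and (R1, kinship) for
parent–offspring (PO), full siblings (FS), 2nd-degree (HS), first cousins
(C1) and unrelated (UR) pairs do not overlap no matter what the underlying
allele-frequency spectrum is (PO touches FS in the single point (0.5, 0)),
so pairs can be classified without frequencies and robustly to SNP
ascertainment. The `expectations` module computes those regions; the
`classify` module implements nearest-reference-point classification in the
(R1, R0) plane and the standard kinship-band scheme with an R0 < 0.02 rule
separating PO from FS.

For low-depth sequencing data the nine counts are estimated by EM on
genotype likelihoods instead of counted: either from the two-individual 2D
site-frequency spectrum (3-genotype likelihoods, a designated allele per
site) or from all 100 pairs of the 10 possible genotypes (no allele
information needed), collapsing onto A–I and discarding pairs with more
than two distinct alleles. Standard errors for every statistic come from a
weighted leave-one-chromosome-out block jackknife.

A full synthetic-data generator (founder-haplotype pairs built by per-site
IBD-state sampling, Poisson-depth reads with a GATK-model likelihood,
MAF-ascertainment filtering, Balding–Nichols cross-population pairs and
RADseq-like 200-bp window subsetting) provides validation data end to end.

## Worked example

```bash
# a full-sibling pair: 100k diallelic sites at ~4x depth, 1% base error
pairkin simulate --relationship FS --n-sites 100000 --seed 7 --depth 4 \
    --out-prefix fs
# estimate the statistics from the genotype likelihoods by EM,
# with chromosome-jackknife standard errors, then classify
pairkin em --beagle fs.beagle.tsv --out fs.em.tsv
pairkin classify --stats fs.em.tsv --out fs.classified.tsv
```

The classified table contains (one row per pair; abbreviated):

```
n_sites       r0        r1  king_kinship     se_r0  se_king_kinship  class_r1r0  class_kinship
 100000 0.077819  0.668527      0.247033  0.003585          0.00308          FS             FS
```

Read: the estimated R0 (0.078) is well away from the PO value 0 but inside
the full-sibling range, R1 (0.669) and kinship (0.247 ≈ 1/4) match the
full-sibling expectation, and both classification schemes label the pair
FS — from 4x data without calling a single genotype. The same table from
`pairkin count`/`pairkin jackknife` works on accurate genotypes (VCF or
TSV), and `pairkin em --gl10 ... --mode ibs` runs the allele-free
IBS estimator.

## Scope

`pairkin` consumes genotypes or genotype likelihoods, not BAM files;
computing likelihoods from alignments (with mapping/base-quality filters)
is upstream of this package. Inbred or admixed individuals violate the
model's assumptions, as they do for most relatedness estimators; the
cross-population shift of R0 (and of Lee's statistic, also provided) can
flag such pairs but not correct for them.
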