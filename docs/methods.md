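# Methods

`autokin` estimates pairwise relatedness `r` in autopolyploids three ways —
from a pedigree, from tracked simulations, and from markers — and provides
the machinery to compare them. This note records the models, the defaults
and why, and the places where a design choice was genuinely open.

## Expected relatedness from a pedigree

For gametic ploidy `v` (somatic allele count `2v`), relatedness and kinship
are linked by `r_XY = 2v * theta_XY`. The recursion computes, in pedigree
order:

- `r_XO = (r_XP + r_XQ) / 2` for offspring `O` of `P` and `Q` and any
  earlier `X`;
- inbreeding `F_O = [C(v,2)(gamma_P + gamma_Q) + v^2 theta_PQ] / C(2v,2)`,
  where `gamma = alpha + (1 - alpha) F` is the within-gamete IBD
  probability and `alpha` the double-reduction fraction;
- `r_XX = 1 + (2v - 1) F_X`.

Assumptions: founders are unrelated, non-inbred and carry unique alleles;
`alpha` is a single population-level scalar (no per-locus variation);
selfing is allowed (`P = Q`). Unknown parents act as unique virtual
founders contributing `theta = 0` and `gamma = alpha`; individuals with
*both* parents unknown are founders and are pinned at `F = 0` regardless of
`alpha` (double reduction only accrues to recorded offspring). `alpha` is
forced to 0 for diploids, where a gamete carries a single allele.
Double reduction enters only through the gamete term `gamma`; the
off-diagonal averaging rule is left untouched, since splitting `alpha`
into the cross terms has no support in the recursion's derivation.

Pedigree files are canonically re-ordered by (generation depth, id). The
tie-break is deliberately *not* input order: the same pedigree parsed from
shuffled rows must yield the identical table, which an order-preserving
tie-break cannot guarantee.

Correctness anchors: an independently coded diploid tabular-method
A-matrix, and Monte-Carlo gene dropping at every ploidy (below).

## Meiosis simulator

Founder homologs carry globally unique integer labels, so label identity
is identity-by-descent by construction. Per chromosome and meiosis:

- **Bivalent mode** — the `2v` homologs are partitioned uniformly at
  random into `v` pairs; each pair emits one chromatid as a mosaic walk
  starting on a random member and switching partners at crossover points
  drawn as a Poisson process at 1 event/Morgan (Haldane: no interference,
  no obligate chiasma; the paper's simulator settings are not published,
  so the minimal stated-information model is used). A duplex tetraploid
  AABB then produces gametes AA:AB:BB = 1:4:1, the exact
  random-chromosome-segregation ratio. (The corresponding selfed-F2
  segregation is 1:8:18:8:1 with homozygote share 2/36; a printed 2/16
  figure circulating for this example does not match exact enumeration
  and is not reproduced.)
- **Quadrivalent mode** — with probability 2/3 (4x), 9/10 (6x) or 24/25
  (8x) per chromosome (configuration constants for "natural pairing",
  taken as given rather than derived from an end-pairing model), four
  random homologs form a ring; ring-adjacent homologs pair, and the
  pairing switches at a single exchange point drawn uniformly on the
  chromosome. Two of the four centromeres are sampled and each emits one
  mosaic chromatid under the position-dependent pairing; leftover
  homologs form bivalents. Double reduction *emerges* when both
  chromatids carry the same parental homolog segment at a locus — no
  rate is ever injected, and observed rates are reported rather than
  asserted. With the default centromere at position 0, the emergent DR
  rate rises with distance from the centromere (~13% at 100 cM for a
  tetraploid, zero exactly in bivalent mode).

Whether the exchange point should be drawn per arm or per chromosome is
unknowable from the available description; one point per chromosome was
chosen. One quadrivalent at most forms per chromosome set.

The default genome is 10 chromosomes x 100 cM with a locus every 0.1 cM
(10,000 loci), the spacing closed at the right end so the count is exact.

**A caution on emergent double reduction.** Realized relatedness (next
section) counts *multiset* allele sharing. Duplicated alleles inside a
gamete reduce expected multiset overlap even though pair-sampling kinship
`2v*theta` is unchanged, so under quadrivalent pairing the mean realized
full-sib relatedness sits visibly below 0.5 (~0.46 for a tetraploid with
this model's genome-average DR rate). Mean-invariance checks in the test
suite are therefore stated under bivalent pairing; estimator-accuracy
comparisons are unaffected because estimator and truth see the same
populations.

## Realized relatedness

At each locus the number of alleles shared IBD by a pair is the multiset
intersection `i` of their 2v-allele label multisets (each Delta_i is an
indicator for tracked data); realized relatedness averages `i/(2v)` over
loci. Benchmarks always evaluate truth and estimator on exactly the same
locus subset. The diagonal (identically 1) is excluded from all benchmark
statistics.

## Marker-based estimators

Dosage (biallelic) methods, on reference-allele counts 0..2v:

- **VR** `A = ZZ' / sum_l s_l^2`, `Z` column-centered dosages, `s_l^2` the
  observed (denominator-n) dosage variance — the literal "variance of the
  locus", not the binomial `2v p(1-p)` (kept as the default; the observed
  variance makes the diagonal average 1 in an unstructured sample).
- **PD** collapses every heterozygous dosage to 1 (pseudo-diploid), takes
  `p_l` from the *recoded* matrix, and averages
  `(m_x - 2p)(m_y - 2p)/(2p(1-p))` over loci with `0 < p < 1`.
- **FA** expands each locus into 2v+1 genotype-class indicators scored by
  class frequency `p'`; empty/full classes drop from the numerator while
  the denominator stays `(2v+1)L` — this fixed denominator is what
  compresses FA estimates toward zero.

Multiallelic similarity methods, on within-genotype allele frequencies
`S_ijx` vs sample frequencies `p_ij` over polymorphic loci:

- **LO** `r = 2v * sum(S_x - p)(S_y - p) / sum p(1-p)`;
- **RI** kinship `theta = 2v * sum(sum_i S_x S_y / p - 1) / sum(k_j - 1)`
  normalized by the pair's self-kinships, `r = theta_XY (1/theta_XX +
  1/theta_YY)/2` — the leading constant cancels and self-relatedness is
  exactly 1; non-positive self-kinship renders a pair undefined;
- **WE** `r = 2v * (sum S_x S_y - sum p^2) / (L - sum p^2)`.

The `2v` prefactor of LO/RI/WE is the product 2·v, consistent with
`r = 2v*theta` (factor 2 in diploids); the FA prefactor is `1/((2v+1)L)`,
the reading consistent with five genotype classes in a tetraploid.

Allele frequencies are plain sample counts including the focal pair, with
no small-sample correction. The practical consequence, visible in the
calibration tests: estimates are centered relative to the *sample*, so in
small or related samples everything shifts down by roughly the mean
sample kinship, and LO additionally carries an `O(2v/n)` negative bias
from plugging estimated frequencies into `p(1-p)`. With ~100 genotyped
individuals the shifts are below the benchmark's 0.05 IC half-width; with
13 they are not. Monomorphic loci (and FA's empty classes) are dropped
and counted in each result's metadata. With missing data each pair is
evaluated on its pairwise-complete loci; a pair with fewer than the
required usable loci comes back NaN.

## Benchmark engine

Scenarios cross 7 ploidy-meiosis combinations, 8 locus counts
{5,...,1000}, 7 allele counts {2,...,20} and 5 founder-allele
distributions (uniform and triangular at every allele count; binomial
1:3 / 1:4 / 1:9 biallelic only): 952 cells, default 100 replicates each.
Founder-allele recoding maps each distinct founder label to a code drawn
iid from the distribution, per locus, then recodes all descendants through
the same map, preserving IBD classes; loci can come out monomorphic by
chance and are counted. Locus subsets are simple random samples without
replacement across the genome.

Metrics: Pearson rho, Lin's CCC
(`2 rho s_e s_o / (s_e^2 + s_o^2 + (mu_e - mu_o)^2)`), RMSE, and IC — the
percentage of estimates within a *closed* ±0.05 band of the realized
value. All off-diagonal pairs of a replicate are pooled; by default each
statistic is computed per replicate and then averaged (mean ± SD across
replicates), with a pooled-across-replicates mode available. Biallelic
methods run only on 2-allele scenarios. Because PD and FA compress toward
zero, their IC on near-zero relationships is high even when rho is poor —
both numbers are always reported so that this artifact is visible.

The full grid at 100 replicates is hours of CPU and sits behind `--full`;
the default demo grid is a stratified ~20-scenario subset at 10
replicates. The accuracy helper used by the acceptance script runs the
common-relationships fixture (13 individuals: six founders plus one
instance of each textbook relationship) at 100 biallelic loci for 25
replicates, sized to finish in well under a minute.

## Numerical conventions

- Every stochastic entry point takes an explicit seed or
  `numpy.random.Generator`; replicate streams are spawned from a root
  `SeedSequence` so runs are reproducible and replicates independent.
- Allele codes in files are positive integers; `0`/empty/`NA` marks an
  unknown parent in pedigrees; `NA` is the universal missing token.
- Relationship matrices are validated symmetric to 1e-9 on read.
- Degenerate inputs fail loudly: all-monomorphic dosage panels, empty
  locus subsets, binomial distributions with k != 2, quadrivalent mode in
  diploids.

## What the simulations do and do not show

The generator reproduces polysomic inheritance with linkage, unique
founder alleles, and allele-number/frequency ascertainment. It does not
model genotyping error, dosage-calling noise, preferential pairing, mixed
cytotypes, or linkage disequilibrium among founders (markers are fully
"effective"); real-data marker requirements will therefore be at least as
large as the simulated ones. Pedigree-expectation agreement is exact only
in mean; individual pairs fluctuate with Mendelian-sampling SD that
shrinks with ploidy and grows with multivalent pairing.
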