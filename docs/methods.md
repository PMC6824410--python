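# Methods

This note documents the statistical models behind `merinoscan`, the
parameters that matter, what the synthetic cohorts do and do not emulate,
and the numerical choices taken where the design was genuinely open.

## Data model and conventions

Genotypes are diploid biallelic dosages (count of the reference allele,
0/1/2, NaN for missing) over a physical map with 1-based positions;
**all intervals are closed** `[start_bp, end_bp]` and a shared boundary base
pair counts as overlap. Sheep autosomes are chromosomes 1–26. For plain
4-column MAP input the reference allele of a SNP is the first allele
encountered in PED file order (deterministic and reproducible from the
files); `write_plink` emits a 6-column MAP carrying the ref/alt characters
(the `.bim` layout) because a bare PED cannot preserve dosage polarity for a
SNP whose first written genotype is homozygous for the alternate allele.

Quality control applies, in a fixed order, sample missingness (> 0.1
removed), SNP missingness (> 0.01), minor allele frequency (< 0.005), and
the autosome filter, with PLINK's threshold semantics. The order is a
declared convention: reversing sample/SNP filtering can change results at
the margin, and each removed item records exactly one (first-failing)
reason.

## Local ancestry

A two-way admixed individual's genome is a mosaic of ancestry blocks. With
`g` generations since admixture and per-bp recombination rate `r`, block
boundaries form approximately a Poisson process of rate `g*r` per bp
(expected block length `1/(g*r)` ≈ 14 Mb at the defaults g=7, r=1e-8).

* **Global proportion α** — supervised maximum likelihood: each sample's α
  maximises the product over SNPs of Binom(2, α·f_A + (1−α)·f_B) at its
  dosages, solved by bounded scalar optimisation on [0, 1] to 1e-6. This
  requires only the two proxies' allele frequencies, not haplotype panels.
* **Windowed diploid calls** — for each window of `window_snps` contiguous
  SNPs (default 50; never spanning a chromosome boundary, truncated with a
  warning if a chromosome is shorter) and each sample, the three states
  s ∈ {0,1,2} Merino copies are scored by the product of genotype
  likelihoods at the state's mixed frequency (s/2)f_A + (1−s/2)f_B times a
  Binom(2, α) prior; the MAP state is the window call. Each SNP receives one
  call per staggered offset (default `n_offsets` = 5) and its dosage is the
  majority vote, computed as mean-then-round-half-up so that exact ties
  break toward more Merino ancestry (a declared, logged convention). The
  window default is tuned to be far shorter than the expected block
  (~2.5 Mb at 50K density vs ~14 Mb), so a window almost always lies inside
  one block.
* **MAA and regions** — MAA(s) = mean over samples of dosage/2; a SNP is
  significant iff MAA strictly exceeds the genome-wide mean *and* reaches
  the genome-wide (not per-chromosome) top-5% nearest-rank quantile, ties at
  the threshold included. Significant SNPs within `merge_gap_bp` (default
  5 Mb — a declared, configurable choice; no published merge rule exists for
  this step) merge into regions scored by their maximum MAA.

## Bayesian F_ST outlier scan

For locus i and population j, allele counts follow the beta-binomial
obtained by integrating the population frequency out of a binomial sampling
layer with a Balding–Nichols drift prior around the ancestral frequency
q_i ~ Uniform(0, 1), with drift intensity

    logit(F_ij) = a_i + b_j,   b_j ~ Normal(−2, 1.8²),

and a spike-and-slab prior on the locus effect: a_i = 0 (neutral) with
prior odds 10, otherwise a_i ~ Normal(0, 3²). Divergent selection appears
as a_i > 0 shared across population backgrounds.

The sampler is Metropolis-within-Gibbs, vectorised across loci (per-locus
parameters are conditionally independent given the b_j): logit random walks
for q_i, a random walk for included a_i, scalar updates for b_j (alternating
populations), and **Gibbs variable selection** for the inclusion indicator.
While a locus is excluded, its dormant effect is refreshed from a
data-informed pseudo-prior centred on the moment-estimator logit F_ST
(linking density sd 1.0); flips into the selection model therefore propose
effects that already fit the data, and the pseudo-prior cancels exactly from
the posterior over included states. Without this, inclusion flips propose
from the vague slab and mix far too slowly to be usable.

Proposal scales are tuned in pilot runs toward 30–35% acceptance. Two chain
presets exist: `default` (10×1000 pilot, 5,000 burn-in, 50,000 kept thinned
by 10) and `desk` (3×300, 1,500, 10,000 thinned by 5), the latter sized so a
2,000-locus two-population scan runs in ~25 s; the calibration tests
(recall ≥ 80% on planted outliers, realized FDP ≤ 0.10, ≤ 1% calls under
neutrality) pass at the desk preset. Convergence is monitored by split-half
R-hat on the population effects (tolerance 1.1); failures flag, never
silently drop, the result.

Reported quantities per locus: the posterior inclusion probability
pip = P(a_i ≠ 0 | data); the posterior-FDR q-value (running mean of 1−pip
down the pip ranking, monotonised by cumulative minimum from the bottom);
and the posterior mean **realized differentiation**, computed by drawing the
two population frequencies from their exact beta conditional at every kept
iteration and evaluating (p₁−p₂)²/(4 p̄(1−p̄)). The realized measure varies
locus-by-locus with the data (rank agreement with the Weir–Cockerham moment
estimator ≥ 0.98 under neutrality), whereas the model parameter
expit(a_i + b_j) collapses to a constant at all never-included loci.

The independent cross-check is the Weir–Cockerham variance-components
estimator computed from allele counts (two-level ANOVA: populations /
alleles within populations); loci monomorphic in both samples are undefined
(NaN), and small negative estimates are legitimate sampling noise.

Consensus: per SNP, N = number of pair-wise comparisons with q < 0.05.
Regions are built seed-and-extend: seeds need N ≥ 4, extension chains over
N ≥ 1 SNPs while **consecutive chained SNPs** are ≤ 200 kb apart (the
chained reading of the linking rule; the seed-anchored alternative fails to
reproduce the reference region ends), and chains from different seeds that
touch merge.

## Runs of homozygosity

ROH are found by exact maximal-run enumeration: per sample and chromosome,
maximal runs of consecutive non-missing homozygous SNPs, split wherever the
inter-SNP gap exceeds 250 kb, kept iff ≥ 25 SNPs, span ≥ 500 kb, and
segment-level density n_snps/length ≥ 1/100 kb. With zero
heterozygote/missing allowance the heuristic scanning window used by PLINK
coincides with exact enumeration, and exactness permits an independent
all-windows oracle in the tests. The 500 kb minimum is the only viable
reading of the stated minimum length (its literal value exceeds every ovine
chromosome).

Incidence(s) = fraction of the cohort's animals with an ROH covering SNP s
(an animal counts once however many of its segments cover s). The island
threshold is the nearest-rank 99.9th percentile of the incidence
distribution *including zeros* (configurable; whether zeros belong in the
distribution is not externally specified), ties included — but a SNP with
zero incidence is never an island member even when sparse data drive the
threshold itself to zero, since "appears in no ROH" cannot evidence an
autozygosity hotspot. Islands are maximal runs of map-consecutive flagged
SNPs; single-SNP islands are legal. Cross-breed overlap records every
island pair from two breeds sharing ≥ 1 bp, with the closed intersection
[max(starts), min(ends)].

## Integration

"Shared by k breeds" admits two readings, and the reference interval lists
are internally consistent only with both being available:

* **strict-intersection** — maximal sets of per-breed intervals with a
  common point (maximal cliques of the interval graph, enumerated at
  interval start points), combined interval [max(starts), min(ends)];
* **chained-overlap** — connected components of the interval-overlap graph,
  combined interval = the component hull.

The four-breed chromosome-17/18 signals match strict intersection; the
three-breed chromosome-5 signal has an empty triple intersection and exists
only as a chain. Every output row names its mode.

Multiple testing across comparisons is handled exactly as the consensus rule
implies — per-comparison q-values, then counting — with no additional
genome-wide correction layered on top.

## Synthetic cohorts: what they emulate, and what not

* Ancestral proxy panels: Balding–Nichols frequencies around ancestral
  p ~ Uniform(0.05, 0.95) (bounds avoid near-monomorphic SNPs);
  the drift parameter F is recovered by the Weir–Cockerham estimator to
  ±0.01 at F = 0.05 in the tests.
* Admixed cohorts: haplotype mosaics with Poisson(g·r per bp) breakpoints
  (the simpler `g·r` rather than `(g−1)·r` rate — documented so recovery
  tests use the same constant), block ancestry A with probability α, raised
  to α + δ for blocks covering planted excess loci; alleles drawn from the
  block panel's frequency; haplotypes are phased internally but only
  unphased genotypes are exposed, matching the real data type.
* Differentiated pairs: neutral Balding–Nichols background plus planted
  outliers constructed with *exact* parametric divergence — frequencies
  displaced symmetrically about an ancestral p ∈ (0.25, 0.75) by
  ±√(F_out·p(1−p)) with random sign, so Var(p_j)/(p̄(1−p̄)) = F_out. An
  independent high-F redraw would leave a large fraction of "outliers"
  undifferentiated by chance (both populations drifting to the same allele),
  making them meaningless as ground truth.
* ROH cohorts: planted tracts forced homozygous; background heterozygosity
  (default 0.4) keeps chance runs far below the 25-SNP minimum (geometric
  run-length tail).

Not emulated: linkage disequilibrium beyond block/frequency structure,
mutation, genotyping error inside ROH, coalescent ancestry, three-way
admixture. Consequently the recovery tests demonstrate correctness of the
inference given the stated generative assumptions — not robustness to
array-specific artefacts of real 50K data.

## Problem sizes and determinism

Calibration tests use 2 × 2,500 SNPs at 50 kb spacing (two ~125 Mb
chromosomes) with n = 100 and 20 seeds for ancestry recovery, and 2,020
loci with n = 50/50 and 10 seeds for the outlier scan at the desk MCMC
preset; these sizes give per-seed Monte-Carlo error comfortably inside the
asserted tolerances. Every generator and the sampler are deterministic
given their seed; the pipeline derives all stage seeds from one master seed
and records every configurable decision in its manifest.

## Known limitations

* The scan assumes exactly two populations per comparison; hierarchical
  multi-population variants are out of scope.
* α estimation is supervised (proxy frequencies known); the unsupervised
  mode is out of scope, and biased proxies bias α and the window prior.
* The windowed ancestry caller reports hard diploid dosages; uncertainty is
  only reflected through the offset vote, not as posterior probabilities.
* q-values calibrate the *posterior-expected* FDR; with few loci (< 100) the
  empirical FDR is unstable and the scan warns.
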