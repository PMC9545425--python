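# Methods

`knotpop` implements the population-genomic workflow used to reconstruct the
recent evolutionary history of a globally distributed migratory shorebird
(the red knot, *Calidris canutus*) from reduced-representation (nextRAD-style)
SNP genotypes: quality control of a multi-sample SNP matrix, classical
diversity and differentiation statistics, coalescent simulation of
user-defined divergence/admixture scenarios, and approximate Bayesian
computation with random forests (ABC-RF) for scenario choice and posterior
parameter estimation.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Genotype data model

Genotypes are diploid ALT-allele dosages in {0, 1, 2} with an explicit
missing sentinel, indexed by sample and by variant.  Variants carry (contig,
1-based position, ref/alt, RAD locus id, indel flag).  The RAD locus — a
150-bp fragment, by default one per contig as in a de novo RAD reference —
is the unit of linkage: bootstrap resampling (F_ST confidence intervals, NJ
node support) and per-locus statistics (Tajima's D, ABC summaries) operate
on loci so that physically linked SNPs travel together.  Dosages always
count ALT alleles as written in the VCF; minor-allele frequencies are
derived downstream, never by re-polarising storage.

## Quality-control chain

Stage order and default thresholds (all configurable): per-variant call rate
≥ 0.80; minor-allele count ≥ 10; indel removal; failed samples (> 90%
missing); Hardy-Weinberg exact test p < 0.05 in at least 6 populations;
LD pruning at r² > 0.20 (window 50 SNPs, step 5); per-sample missingness
> 25%; PI-HAT relatedness > 0.20.  Threshold semantics are literal: "below
80%" removes strictly below, "above 25%" strictly above.  Each stage records
before/removed/after counts for both dimensions, and the report enforces the
telescoping identity before − removed = after across the chain.

Numerical choices:

- **HWE** uses the two-sided exact test with probability-mass ordering,
  enumerating every heterozygote count consistent with the observed allele
  counts in log space; monomorphic input returns p = 1.  The exact test is
  fully enumerable for RAD-scale samples and is the standard for SNP QC.
  Populations contributing fewer than two called genotypes at a variant
  count as "no deviation".
- **LD pruning** is greedy within a sliding window: while any retained pair
  exceeds r² (dosage correlation over pairwise-complete genotypes), the
  member with the lower call rate (ties: higher index) is removed.  The
  window/step are conventions — the threshold is the filter; the retained
  set provably contains no within-window pair above the threshold.
- **PI-HAT** is the plain method-of-moments IBD estimator: expected IBS
  class probabilities under IBD ∈ {0,1,2} from plug-in allele frequencies
  (estimated on the full retained sample), solved sequentially and truncated
  to the probability simplex; PI-HAT = P(IBD=2) + P(IBD=1)/2.  Pairs with
  fewer than 50 co-called variants are flagged low-confidence.  *Known
  limitation:* the estimator assumes a homogeneous sample.  Across strongly
  diverged populations, pooled frequencies under-predict within-population
  allele sharing, inflating within-population PI-HAT; with few SNPs the
  simplex truncation adds a further upward bias.  On strongly structured
  synthetic data the demo pipeline therefore raises the threshold; on real
  data of the weak-structure kind this tool targets, the default 0.20 is
  appropriate.
- **Relatedness resolution** removes, iteratively, the sample in the most
  offending pairs (ties: higher missingness, then lexicographic id) until no
  pair exceeds the threshold — a deterministic greedy vertex cover.

## Diversity and differentiation

- Per-site nucleotide diversity π = 2·n_minor·n_major / (n·(n−1)) over
  called alleles; sites with fewer than two called alleles are excluded.
- Observed heterozygosity is the fraction of called genotypes that are
  heterozygous; the per-individual inbreeding coefficient is
  F = (O_hom − E_hom)/(N − E_hom) with the unbiased expected-homozygosity
  correction 2p(1−p)·2n/(2n−1), restricted to each individual's called sites.
- Tajima's D is computed per RAD locus within each population with the
  standard a₁…e₂ constants; the allele sample size is the rounded mean
  number of called alleles over the locus's segregating sites, and loci with
  no segregating site (or n < 4) are undefined and excluded from means.
- F_ST is the two-population Weir–Cockerham variance-components estimator
  with multi-locus aggregation as a ratio of sums Σa / Σ(a+b+c) across
  sites — not a mean of per-site ratios, which is biased for
  low-information sites.  Negative estimates are retained so that averages
  and interval coverage stay unbiased.  Confidence intervals are percentile
  bootstrap over RAD loci (default 500 replicates); p-values come from
  permuting individuals' population labels, p = (1 + #{θ* ≥ θ}) / (n_perm+1)
  (default 1,000 permutations).
- Nei's genetic distance defaults to the *minimum* distance
  Dm = mean over sites of (Jx+Jy)/2 − Jxy (Jx = Σp²); the 1972 standard
  distance −ln(Jxy/√(JxJy)) is available by option, since published usages
  name both variants.  Allele frequencies are computed over called alleles,
  the frequency-level equivalent of replacing missing data by mean allele
  counts.
- Neighbour joining uses the Saitou–Nei Q-criterion (via scikit-bio), exact
  on additive matrices; node support is the percentage of locus-bootstrap
  replicates containing each bipartition of the full-data tree.
- PCA normalises each variant by centring at its mean dosage and scaling by
  √(p(1−p)), mean-imputes missing cells (zero after centring), drops
  monomorphic variants, and eigendecomposes the sample covariance.
  Mean imputation matches the NJ treatment of missing data; no probabilistic
  imputation is attempted.

## Coalescent scenario simulator

Scenarios are declarative YAML: sampled populations with diploid sample
sizes and effective sizes, plus an ordered backward-time event list of
merges (lineages move from a source into a destination branch), pulse
admixtures (each lineage of the target moves to source1 with probability r,
else source2; a founding pulse empties the target), and size changes.  Any
numeric field may name a parameter bound to a prior (uniform or
log-uniform, with pairwise order constraints enforced by rejection
sampling).

Per locus, the simulator runs a continuous-time Kingman coalescent: k
lineages in a population of diploid size N coalesce at rate k(k−1)/(4N) per
generation; events fire at their scheduled times; simulation continues to a
single root lineage.  Exactly one mutation is then placed uniformly at
random on the total branch length — fixed-S conditioning, which reproduces
the ascertainment of discovered SNPs and matches the SNP-mode simulation
design of DIYABC-style ABC tools.  No mutation rate enters the simulation;
the Charadriiformes substitution rate (1.5 × 10⁻⁹ /site/year) and the
6-year generation time are used only for converting reported estimates.
The frequency spectrum this produces is E[ℓᵢ/L] — *not* the unconditional
1/i spectrum — and is validated against an independent coalescent
implementation (msprime) in the test suite.

Missingness is independent per-call masking at per-population template
rates (default 4.5%, the genotyping completeness of the kind of dataset the
generator emulates); loci monomorphic after masking are redrawn so the
locus count stays fixed.  One master seed drives counter-based per-locus
streams, so results are reproducible and independent of evaluation order.
The inner loop is compiled with numba; a dataset of 80 diploids × 1,000
loci simulates in well under a second.

The bundled scenario library encodes the two-step model-choice design for
the eight red knot breeding populations (rufa, islandica, canutus,
piersmai, rogersi 1/2, roselaari W/E): four Step-1 backbone rootings and
nine Step-2 refinements of the winning rooting, including the
best-supported Step-2 scenario (old admixed origin of piersmai from the
rogersi branch and canutus; recent admixed origin of islandica from rufa
and canutus; a pulse from roselaariE into the Nearctic branch).  The
topologies are reconstructions from published prose; prior ranges bracket
the published posterior 95% credible intervals rather than reproducing the
original supplementary prior tables, and each file says so.  The
best-supported scenario carries a `truth` block: published posterior means
where printed (e.g. oldest split 5,619.7 generations = 33,718 years;
islandica admixture fraction from rufa 0.67), and fixed reference values
chosen once inside the prior brackets for the parameters the publication
does not print (three divergence/admixture times, the roselaariE pulse rate
0.2, and ancestral sizes of 20,000).

## Summary statistics

The fixed summary vector contains, per population, the proportion of
monomorphic loci and the mean/variance across loci of unbiased gene
diversity 2p(1−p)·n/(n−1); per population pair, the mean/variance of
per-locus Weir–Cockerham F_ST, the mean Nei minimum distance, and the
proportion of loci monomorphic in the pooled pair; and per admixture trio
(target | source1, source2), the mean/variance of a per-locus least-squares
admixture coefficient: the a minimising Σ(p_T − a·p₁ − (1−a)·p₂)² over the
locus's sites, clipped to [0,1].  The published pipeline's exact trio
statistic is not specified in the main text; the least-squares coefficient
is this package's documented stand-in.  It is exact when the target copies
a source, and attenuates toward 0.5 on loci where the sources barely differ
(sampling noise dominates the clipped ratio) — the RF consumes it jointly
with the pairwise statistics, which restores identifiability.  Degenerate
cells have defined fallbacks (pair with no informative loci → 0/0; trio
with identical sources → 0.5/0), so vectors never contain NaN.  For 8
populations and 2 trios the vector has 140 entries; linear discriminant
axes (n_scenarios − 1 of them, fitted on standardised training summaries
with a ridge-stabilised pooled covariance, never on the observed vector)
are appended for scenario choice.

## ABC random forests

**Scenario choice** trains a classification forest (√p features per split)
on the reference table; votes are the per-tree predictions at the observed
vector, the prior error rate is the out-of-bag misclassification fraction,
and the posterior probability of the selected scenario is the prediction,
at the observed point, of a regression forest trained on the out-of-bag
indicator "OOB-classified scenario equals true scenario" — the standard
ABC-RF recipe.

**Parameter estimation** trains one regression forest per parameter
(min leaf size 5; p/3 features per split, floored at 5 so small summary
vectors are not reduced to single-feature splits).  Posterior weights are
leaf co-occurrence weights over all training rows: for each tree, rows
sharing the observed point's terminal leaf receive weight 1/(leaf size),
averaged over trees and normalised.  Posterior mean, median and 2.5%/97.5%
quantiles come from the weighted empirical distribution; the degenerate
case of a constant parameter returns a zero-width posterior at that
constant.  Time parameters are reported both in generations and in years
(× 6 years/generation).

Desk-scale defaults are deliberately reduced relative to publication-scale
ABC practice (tens of thousands of simulations per scenario, 100,000 for
estimation): the bundled recovery analyses use 2,000 prior draws of
8 populations × 10 diploids × 500–1,000 loci and 500–1,000 trees.  At this
scale the weighted posterior mean of a deep split time carries visible
shrinkage/bias — on the bundled best scenario the oldest split is
systematically recovered near 46k years against a generating 33.7k, inside
the published 95% credible interval — while admixture fractions, which the
trio statistics measure almost directly, recover within a few percentage
points.  The parameter-recovery tests therefore check interval-level
agreement, not point equality.

## What the synthetic tests show — and what they do not

The generator reproduces the *structure* of the real data (8 populations of
diploid RAD genotypes, unlinked ascertained SNPs, population-specific
missingness, divergence/admixture history) but not its nuisance features:
no genotyping error, no depth-dependent dropout, no reference bias, no
within-locus multi-SNP haplotype structure, and pulse admixture only (no
continuous migration, recombination or selection).  Green tests demonstrate
internal correctness (estimators match independent oracles; the simulator
matches coalescent theory; inference recovers parameters of its own
generative model) — they do not certify the published real-data values,
which require the deposited genotypes and publication-scale simulation
budgets.  The pipeline computes all of those quantities when given such
data.

## Known limitations

- PI-HAT inflation under strong structure (above).
- LD pruning on strongly structured samples removes ancestry-correlated
  SNPs even when loci are physically unlinked (admixture LD); this mirrors
  the behaviour of the standard tools it reimplements.
- The exact published summary-statistic catalogue (268/272 entries) is not
  reproduced name-for-name; the schema report makes the difference explicit.
- Tajima's D assumes a locus-constant allele sample size; under heavy,
  site-heterogeneous missingness the rounded-mean approximation is coarse.
- NJ tie-breaking follows scikit-bio's deterministic implementation rather
  than a bespoke smallest-index rule; only degenerate (star-like) matrices
  are affected.
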