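# knotpop

Population-genomic analysis of global flyway populations from
reduced-representation (RAD-style) SNP data: quality control, diversity and
differentiation statistics, coalescent simulation of divergence/admixture
scenarios, and ABC random-forest demographic inference.

The package targets the workflow used to reconstruct the phylogeographic
history of the red knot (*Calidris canutus*), an arctic-breeding migratory
shorebird with eight analysed breeding populations — but every component is
generic: any multi-sample VCF of biallelic SNPs with a sample→population map
can be pushed through the same chain.

## What it computes

**QC** (`knotpop.variant_qc`) — call-rate, minor-allele-count, indel,
Hardy-Weinberg (exact test, per population), LD-pruning (r² > 0.20),
per-sample missingness and PI-HAT relatedness filters, with exact
before/removed/after bookkeeping per stage.

**Statistics** (`knotpop.popgen_stats`) — per-site nucleotide diversity π,
observed heterozygosity and individual inbreeding F, per-locus Tajima's D;
pairwise Weir–Cockerham F_ST

θ̂ = Σ_sites a / Σ_sites (a + b + c)

with 95% bootstrap CIs over RAD loci and label-permutation p-values; Nei
minimum/standard genetic distances; neighbour-joining population trees with
bootstrap node support; genotype PCA with √(p(1−p)) normalisation.

**Simulation** (`knotpop.scenario_engine`) — a continuous-time Kingman
coalescent over declarative YAML scenarios (population merges, pulse
admixtures, size changes; parameters bound to priors with order
constraints).  Each unlinked 150-bp locus carries exactly one SNP placed
uniformly on the tree, reproducing the ascertainment of discovered
polymorphisms; missingness is masked at per-population rates.  Thirteen
scenarios for the eight red knot populations ship with the package,
including the best-supported model: two refugial lineages separating
~34,000 years ago followed by post-glacial divergences and three admixture
pulses.

**Inference** (`knotpop.abc_rf`) — ABC-RF in the statsmodels idiom:
`ScenarioChoiceModel(reference, observed).fit()` returns votes per
scenario, the out-of-bag prior error rate and the posterior probability of
the selected scenario; `ParameterRegressionModel(...).fit()` returns
weighted posterior means/medians/credible quantiles per parameter (leaf
co-occurrence weights), with times convertible to years at 6
years/generation.

## Worked example

Simulate genotypes under the bundled best-supported scenario at its
reference parameter values, then estimate differentiation:

```python
import numpy as np
import knotpop as kp
from knotpop import popgen_stats as ps

spec = kp.builtin_scenario("step2_d")
g = kp.simulate_genotypes(spec.scenario, spec.truth, 1000, missing=0.045, seed=7)
pm = kp.population_map_for(spec.scenario)

theta = ps.wc_fst(g, pm, "rufa", "islandica")
lo, hi = ps.fst_bootstrap_ci(g, pm, "rufa", "islandica", n_boot=500,
                             rng=np.random.default_rng(7))
p = ps.fst_permutation_p(g, pm, "rufa", "islandica", n_perm=1000,
                         rng=np.random.default_rng(7))
print(f"F_ST(rufa, islandica) = {theta:.4f}  95% CI [{lo:.4f}, {hi:.4f}]  p = {p:.4f}")
```

prints

```
F_ST(rufa, islandica) = 0.0607  95% CI [0.0470, 0.0753]  p = 0.0010
```

— the two Nearctic populations are weakly but significantly differentiated
in this realisation (θ̂ is the ratio-of-sums Weir–Cockerham estimator; the
CI resamples loci; the p-value is the smallest attainable at 1,000
permutations).  Per-population summaries come from the same matrix, e.g.
`canutus`: mean π = 0.132, H_obs = 0.136, mean Tajima's D = −0.007
(≈ 0, as expected for neutral constant-size data).

The same analysis runs from the shell:

```bash
knotpop demo-data --out demo --loci 1000 --seed 7
knotpop stats --vcf demo/demo.vcf --popmap demo/demo.popmap.tsv --out run
knotpop abc --scenario step1_a --scenario step1_c --out abc_run --seed 1
```

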