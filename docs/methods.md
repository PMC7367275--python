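# Methods

`geckoabc` reconstructs, as reusable code, a complete island
population-genetics workflow for a species sampled across an archipelago:
descriptive diversity and differentiation statistics for microsatellites and
mtDNA, median-joining haplotype networks, haplotype rarefaction, and
Approximate Bayesian Computation (ABC) over four demographic scenarios that
could explain a weak two-cluster (North/South) partition. Because the
package ships no field data, a synthetic-data module generates
study-shaped pseudo-observed datasets with known ground truth; every claim
the test-suite makes is therefore a claim about the implementation, not
about any particular empirical system.

## Observed-data model

Microsatellite genotypes are diploid fragment-length alleles (base pairs),
with whole-call missingness only: a half-typed call in an input file is
coerced to missing with a warning. GENEPOP input uses the 3-digit-per-allele
encoding (alleles here reach 383 bp, beyond the 2-digit dialect, which is
rejected with an explicit error). mtDNA alignments are equal-length
sequences over {A, C, G, T, N, -}; the population label rides in the FASTA
header after a configurable delimiter (default `|`), and a header without a
delimiter yields population "unknown" plus a logged warning. Islands map to
the two clusters North = {North Andaman, Middle Andaman, Interview,
Baratang, Neil, Long} and South = {Havelock, South Andaman, Little Andaman}
by default; the clustering is an input labelling, not something the package
infers.

## Descriptive statistics

* **Expected heterozygosity** is Nei's unbiased estimator
  `(n/(n-1)) (1 - sum p_i^2)` over `n` non-missing gene copies; the plain
  plug-in version is available behind `unbiased=False`.
* **F_IS** is defined as `1 - Ho/He` per locus-population, with a two-sided
  permutation p-value obtained by re-pairing gene copies among the
  population's individuals (He is invariant under that permutation, so only
  Ho is recomputed). The variance-components definition used by some R
  packages differs slightly in small samples; the ratio definition is used
  here because it is the one the reported statistic names.
* **F_ST** is multiallelic Weir-Cockerham (1984) theta, with the a/b/c
  variance components summed over alleles and loci before the ratio
  ("ratio of sums"). Negative estimates are reported as-is. Permutation
  p-values shuffle individuals between populations. Populations with fewer
  than two genotyped individuals are excluded with a warning.
* **G_ST** for sequences uses haplotype frequencies with the Nei-Chesser
  (1983) small-sample corrections (harmonic-mean sample size; H_T corrected
  by H_S/(r n~)); for undifferentiated populations the correction is
  slightly negative by construction, which is why negative entries are
  legitimate output.
* **HWE**: the primary test is a Monte-Carlo exact test (Guo-Thompson
  style): gene copies are re-paired at random and tables no more probable
  than the observed one (conditional on allele counts) are counted, with an
  add-one correction. A chi-squared variant with `k(k-1)/2` degrees of
  freedom and no pooling of rare classes is reported alongside. Fewer than
  1,000 MC replicates triggers an instability warning.
* **FDR** control is Benjamini-Yekutieli: reject the `i*` smallest p-values
  where `i* = max{i : p(i) <= i alpha/(m c(m))}`, `c(m) = sum 1/j`; the
  reported critical value is `i* alpha/(m c(m))`, zero when nothing is
  rejected.
* **Allele sharing** between two individuals is the multiset overlap of
  their diploid calls summed over loci genotyped in both, divided by twice
  the number of such loci (NaN when none).
* **Sequence diversity**: segregating sites S and total mutations eta
  (`sum(states - 1)` per site) use complete deletion of sites containing N
  or `-`; distances (pi, k, max p) use pairwise deletion; haplotypes are
  defined on the complete retained sites; Hd carries the `n/(n-1)`
  correction. With pairwise deletion pi is the mean per-pair p-distance and
  the reported `effective_length` is the implied `k/pi`.

## Median-joining networks

Sites containing gaps or ambiguity in any sequence are removed before
collapsing (complete deletion, configurable), keeping the construction
deterministic. The network iterates between building the epsilon-relaxed
minimum spanning network over the current node set and adding quasi-median
vectors (per-site majority of MSN triplets; a three-state site contributes
all three options) whenever they reduce the total network cost, defined as
the minimum-spanning-tree weight over the node set in Hamming space. Ties
between equally cost-reducing candidates are broken by adding the
lexicographically smallest sequence, so output is deterministic. Unsampled
nodes of degree <= 2 are pruned to closure; edge labels are Hamming
distances. Epsilon defaults to 0 (most parsimonious). All characters are
weighted 1. On exhaustive small binary instances the greedy construction
empirically attains the exact Steiner minimum (checked against a
Dreyfus-Wagner oracle in the tests); no optimality guarantee is claimed in
general — the algorithm is a heuristic, and the cost-reduction loop merely
guarantees monotone non-increasing cost and termination. One caveat the
tests make explicit: a median-joining network minimises *total* cost, so a
path between two sampled haplotypes can be longer than their direct Hamming
distance; the correct containment property is that the final graph contains
an MST of its own node set.

## Rarefaction

The probability of observing `k` haplotypes among `n` sequences is
estimated by Monte Carlo: each replicate draws `n` sequences *with
replacement* from the empirical pool (the convention of the workflow this
reproduces; classical without-replacement rarefaction is available via
`replace=False`), counts distinct haplotypes, and compares with `k` under
`exactly` (default), `at_most` or `at_least`. The 95% CI is Clopper-Pearson
on the success count. `exactly` is the default reading of "probability of
identifying k haplotypes"; the one-sided reading is a flag away.

## Coalescent simulator

Four scenarios relate the North and South clusters. Scenarios I-III: an
ancestral population (size NA) splits at `t_div` into two precursors
(N3, N4); at `t_admix < t_div` the extant clusters (N1, N2) are each formed
as a 50:50 admixture of the precursors, implemented backwards in time as
independent reassignment of each surviving lineage to precursor 3 or 4 with
probability 1/2. The scenarios differ only in the prior on `t_admix`.
Scenario IV is a plain split at `t_div`. Setting `t_admix = t_div` in
scenario I is structurally identical to scenario IV; the test-suite verifies
this distributional identity by KS tests on every summary statistic
(family-wise alpha 0.01 via Bonferroni across the ~26 statistics — a
per-statistic alpha of 0.01 would produce a ~23% false-alarm rate under the
exact null, which would make the check meaningless).

Genealogies use the continuous-time Kingman coalescent with exponential
waiting times; gene-copy numbers are `2N` (autosomal) and `N/2`
(mitochondrial, females under an even sex ratio; the `N/4`
autosomal-relative convention is selectable). Times are years divided by
`generation_time`, default 1 year/generation (the study system is a small
gecko; the value is configurable and logged).

**Sequence mutation** follows the Kimura two-parameter model: per branch
and site the number of events is Poisson at rate `useq`; each event is a
transition with probability `kappa/(kappa+2)`. Under the A=0,C=1,G=2,T=3
encoding every event is an xor jump, and marginalising the Poisson count
analytically gives the standard K2P transition probabilities per branch;
jumps are therefore drawn in closed form per site and are independent of the
parental state, which lets the whole mutation field be generated before a
single pass propagates sequences down the tree. This is an exact sampling
scheme for the model, not an approximation, and it is what makes
40,000-row reference tables affordable on one CPU.

**Microsatellite mutation** is a generalized stepwise model: per-branch
Poisson events, step magnitude `1 + (Geometric(1 - P_gsm) - 1)` motif units
(mean `1/(1-P_gsm)`; `P_gsm = 0` is the strict single-step model), direction
symmetric, reflecting at the boundaries of a 40-unit contiguous allele
range (a common default for bounded microsatellite ranges). Because step
directions are symmetric, the reflected walk's endpoint has the same
distribution as the triangular fold of the free walk's endpoint, so steps
are accumulated freely down the tree and folded once at the tips. Branches
with more than 64 events use a moment-matched normal for the
signed-geometric sum — by then the walk has mixed over the folded range and
the discrepancy is far below Monte-Carlo resolution; branches at or below
64 events are sampled step-exactly. Per-locus rates are Gamma-distributed
around the across-locus mean (shape 2, truncated to [1e-7, 1e-2]);
independent single-nucleotide indels at rate `sni` shift fragment length by
1 bp outside the motif. Allele size = base length + 4 x repeat count + indel
offset.

## ABC

**Summary statistics** (26): per cluster for mtDNA — haplotype count,
segregating sites, mean and variance of pairwise differences, private
segregating sites (polymorphic in the focal cluster, monomorphic in the
other), mean and variance over segregating sites of the count of the rarest
observed base; across clusters — pooled haplotype count and S, mean
within-cluster and between-cluster pairwise differences, and sequence
F_ST = 1 - within/between clamped to [-1, 1]; for microsatellites — mean
allele number and mean unbiased genic diversity per cluster and pooled, and
the two-cluster Weir-Cockerham theta. Degenerate entries are imputed 0 and
flagged; flagged dimensions of the observed vector are dropped from the
distance for every table row.

**Priors** (uniform unless noted): sizes U(10, 4e6); `t_div`
U(35e3, 4e5) years for I-III and U(10, 6e4) for IV; `t_admix` U(2e3, 35e3)
(I), U(501, 6e3) (II), U(10, 500) (III), drawn subject to
`t_admix < t_div`; admixture proportion fixed at 0.5; `useq` U(1e-9, 1e-4);
`kappa` U(1, 30); mean microsatellite rate U(1e-6, 1e-2); `P_gsm`
U(0.1, 0.3); `sni` U(1e-8, 1e-5). The reference table allocates simulations
equally across the four scenarios (symmetric model prior).

**Rejection** retains the `ceil(tolerance x rows)` closest rows (default
1%) by Euclidean distance on MAD-normalised statistics (zero-MAD columns
fall back to the SD, then to 1). **Model choice**: the direct approach is
the scenario proportion among retained rows with a binomial CI; the
logistic approach regresses the scenario label on the normalised stat
differences with Epanechnikov weights (bandwidth = max retained distance),
evaluated at the observed point, after projecting onto linear-discriminant
axes (at most 3) — the dimension-reduction convention of established ABC
tooling, essential when a few hundred retained rows meet 26 statistics — and
with a mild ridge penalty (C = 10) against quasi-separation; CIs come from
the delta method on the observed information. A failed fit falls back to
the direct approach with a warning. **Parameter estimation** is
Beaumont-style local-linear adjustment: parameters are logit-transformed to
their prior range (guaranteeing adjusted draws stay inside the prior),
regressed on the stat differences with Epanechnikov weights, shifted to
zero difference, back-transformed, and summarised by a weighted-KDE mode
and weighted 2.5%/97.5% quantiles; a singular design degrades to the
rejection-only posterior with a warning. A PCA prior check projects the
observed vector onto the table's first two principal axes and flags a
Mahalanobis percentile above 99.

## Synthetic data

The study-shaped generator uses nine islands with microsatellite sample
sizes (47, 50, 2, 11, 2, 1, 9, 12, 6) summing to 140; the three sizes not
individually reported in the study design (Interview 2, Neil 2, Long 1) are
assumptions chosen to reach the printed total. 13 tetranucleotide loci,
7.4% uniformly random missing calls (a per-locus rate vector is accepted,
since real missingness is heterogeneous), a 123-sequence COI alignment of
403 bp and a 17-sequence 16S panel. Islands are labels only: the
demographic model operates at cluster level and individuals are assigned to
islands in proportion to the design sizes (exactly for genotyped
individuals, proportionally with randomised remainder for sequences). The
generator therefore emulates sample-size structure, missingness and
two-cluster demography, but none of real data's island-level substructure,
null alleles, allele-scoring error or per-locus missingness patterns —
passing tests demonstrate pipeline correctness, not robustness to those
artefacts.

## Validation design and problem sizes

The test-suite validates formulas against independent brute-force oracles
(explicit-loop reimplementations, exhaustive enumeration for the HWE exact
test and BY threshold search, Dreyfus-Wagner for Steiner optimality),
coalescent and mutation moments against closed forms at 10,000 replicates
with 3-MC-SE bands, and the simulator against an external coalescent
simulator (msprime) by a KS test on pairwise TMRCA under a two-population
split.

ABC self-consistency uses a 40,000-row reference table over a reduced
sampling design (20 diploid individuals and 20 sequences per cluster,
13 loci, 403 bp) — one-tenth of the 400,000 simulations a full analysis
would use, with the retained fraction held at 1%. Pseudo-observed datasets
are drawn *from each scenario's own prior*, the standard confusion-matrix
calibration for ABC model choice (fixed-parameter truths far outside the
prior-predictive bulk would test the priors, not the pipeline). Because
scenario II's admixture-time prior is nested inside scenario I's support
and II/III differ only in that prior, exact labels are weakly identified by
construction; the calibration therefore scores group membership — the
recent-admixture group {II, III} against the confounded split/admixture
pair {I, IV} — requiring >= 70% top-posterior group accuracy over 20
replicates, and >= 80% coverage of the true scenario-IV divergence time by
the 95% adjusted posterior interval over 20 replicates (tolerance 2% for
the estimation step so that at least 50 scenario-IV rows are retained).
I-vs-IV confusion is expected and tolerated: with both marker classes, an
admixture event and a plain split at the same effective time produce
nearly identical data, which is precisely the ambiguity the original
analysis reported.

## Numerical choices and degenerate inputs

Monomorphic locus-populations report He = Ho = 0 with F_IS as NaN (never
0). Monomorphic HWE tables give p = 1. Pairs with no comparable sites or no
shared loci give NaN distances. Permutation p-values use add-one
correction. Ties in rejection distances break by row index (stable sort).
The KDE mode falls back to the weighted median if the kernel is singular.
Seeds are mandatory for every stochastic CLI subcommand and all library
randomness flows through an explicit `numpy.random.Generator`.

## Known limitations

No recombination, post-divergence migration, or selection; no
linkage-disequilibrium testing, null-allele inference or clustering (the
North/South partition is an input); GENEPOP files cannot round-trip
population names without a population map; the logistic CI is asymptotic
(bootstrap is not implemented); analytic rarefaction curves are out of
scope. The allele-range bound (40 motif units) and the Gamma shape (2) for
per-locus rates are conventions, not inferred quantities.
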