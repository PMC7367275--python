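# geckoabc

Population genetics, haplotype networks and coalescent/ABC demographic
inference for joint microsatellite + mtDNA datasets from island systems.

The package targets the common situation in archipelago phylogeography: a
species sampled across many islands shows high allelic diversity but weak
geographic structure, with at most a faint two-cluster (North/South)
signal. `geckoabc` provides the full analysis chain for that situation:

* **Descriptive layer** — allele counts, Nei's unbiased expected
  heterozygosity *H*<sub>E</sub>, observed heterozygosity *H*<sub>O</sub>,
  *F*<sub>IS</sub> = 1 − *H*<sub>O</sub>/*H*<sub>E</sub> with permutation
  significance, multiallelic Weir–Cockerham *θ* (pairwise and global, with
  permutation p-values), Nei–Chesser *G*<sub>ST</sub> on mtDNA haplotype
  frequencies, Guo–Thompson Monte-Carlo exact HWE tests plus a χ² variant,
  Benjamini–Yekutieli FDR control, an allele-sharing matrix, and sequence
  diversity (haplotypes, *S*, η, π, *k*, *H*<sub>d</sub>, uncorrected
  *p*-distances).
* **Haplotype networks** — deterministic median-joining (Bandelt–
  Forster–Röhl) construction with quasi-median vectors, exportable to GML.
* **Rarefaction** — Monte-Carlo probability of observing *k* haplotypes in
  a subsample of *n* sequences, for comparing marker panels of different
  depth.
* **Coalescent simulator** — four split/admixture scenarios for a
  North/South cluster pair (ancestral split into precursors with a later
  50:50 admixture at three alternative time scales, or a plain split),
  with K2P sequence mutation and a generalized stepwise (geometric-step,
  reflecting-boundary) microsatellite model.
* **ABC engine** — reference-table construction over the four scenarios,
  a 26-statistic summary vector, rejection on MAD-normalised Euclidean
  distance, model choice by direct counting and by Epanechnikov-weighted
  multinomial logistic regression (on LDA axes), Beaumont local-linear
  parameter adjustment, and a PCA prior check.
* **Synthetic data** — study-shaped pseudo-observed datasets (nine island
  populations in two clusters, 13 tetranucleotide loci for 140 diploid
  individuals with 7.4% missing calls, a 123 × 403 bp COI alignment) with
  ground truth recorded, so the whole pipeline is testable without any
  field data.

The scientific background, model assumptions, numerical choices and
validation design are documented in [`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a study-shaped dataset under the plain-split scenario and run the
descriptive layer:

```python
import numpy as np
from geckoabc import synthdata, sumstats
from geckoabc.coalsim import DemographicScenario, ScenarioParams

params = ScenarioParams(N1=200_000, N2=100_000, NA=20_000, t_div=25_000,
                        useq=2e-8, kappa=5, mu_mic_mean=2e-4, P_gsm=0.2, sni=1e-7)
rng = np.random.default_rng(1)
G, aln, pm, truth = synthdata.generate_pseudoobserved(
    DemographicScenario("IV"), params, synthdata.StudyDesign(), rng)

div = sumstats.locus_diversity(G, pm)
print(sumstats.overall_summary(div).round(2))
print(sumstats.sequence_diversity(aln))
```

```
NA_alleles    21.23
He             0.92
Ho             0.91
dtype: float64
SeqDiversity(n=123, n_hap=10, S=10, eta=10, pi=0.0029235617580924615,
             k=1.1781953885112622, Hd=0.745035319205651,
             max_p=0.01488833746898263, effective_length=403.00000000000006,
             complete_sites=403)
```

A population of a few hundred thousand with these mutation rates gives the
expected signature of such systems: very high microsatellite diversity
(*H*<sub>E</sub> ≈ 0.92, ~21 alleles per locus) alongside modest
mitochondrial diversity (10 haplotypes, π ≈ 0.003, *H*<sub>d</sub> ≈ 0.75)
— many near-identical COI sequences spread across islands.

The same operations are exposed on the command line:

```sh
geckoabc synth --scenario IV --params params.json --seed 1 --out-prefix pseudo
geckoabc stats --genotypes pseudo.genepop.txt --popmap pseudo.popmap.csv \
    --permutations 1000 --seed 2 --out stats.csv
geckoabc hapnet --fasta pseudo.fasta --epsilon 0 --out net.gml
geckoabc rarefy --fasta pseudo.fasta --n 17 --k 6 --reps 10000 --seed 3
geckoabc abc build-table --n-sims 40000 --seed 4 --out table.npz
geckoabc abc fit --observed obs.json --table table.npz --tolerance 0.01 --out fit.json
```

Every stochastic subcommand requires `--seed` and writes a JSON run
manifest so outputs can be replayed bit for bit.

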