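# pharmapop

Population pharmacogenomics for admixed cohorts: quantify how the allele
frequencies of drug-response SNPs ("pharmaSNPs") differ between
populations, tie those differences to individual genetic ancestry, and
validate inexpensive genotyping assays against sequencing-derived calls.

The package is aimed at population-genomics and precision-public-health
analysts who need to decide *which* pharmacogenomic test matters for
*which* population — the motivating case being two neighbouring Colombian
populations with very different admixture profiles: Antioquia (mainly
European ancestry with substantial Native American admixture) and Chocó
(mainly African ancestry).

## What it computes

Given a genotype matrix (VCF), a pharmacogenomic annotation table
(effect / non-effect allele, gene, drug, evidence level), and a
population manifest:

- **Frequency statistics.** Minor allele frequency per variant, and
  Wright's fixation index across populations,
  F<sub>ST</sub> = σ² / (p̄ (1 − p̄)), where p̄ is the unweighted mean of
  the per-population allele frequencies and σ² their variance.
- **Structure.** Greedy windowed LD pruning (pairwise r² threshold),
  pairwise 1 − identity-by-state distances, and classical (Torgerson)
  MDS projection.
- **Ancestry.** Supervised per-individual ancestry fractions **q** on
  the simplex, maximising the binomial likelihood of genotypes given a
  reference panel of component allele frequencies via a multiplicative
  EM update; and per-variant ancestry association by OLS of ancestry
  fraction *y* on effect-allele dosage *x* ∈ {0,1,2}, tested with
  *t* = β / SE<sub>β</sub>.
- **Divergence screen.** Per pharmaSNP, the log frequency ratio
  R = log₂(f₁/f₂), the difference Δ = f₁ − f₂, and the composite
  Euclidean distance from the origin E = √(R² + Δ²); the screen ranks
  high-evidence pharmaSNPs with E > 0.5.
- **Assay concordance.** 3×3 genotype-class confusion matrices
  (homozygous non-effect / heterozygous / homozygous effect) between a
  truth call set and a test assay, with accuracy and one-vs-rest
  sensitivity, specificity, and precision.
- **Synthetic cohorts.** A Balding–Nichols + Dirichlet-admixture
  simulator generates reference panels, two-cohort studies with known
  ancestry truth, annotation tables, and discordance-injected re-call
  sets, so the entire pipeline runs and is tested without any data
  download.

## Worked example

Run the end-to-end synthetic demo (simulate → orient to effect alleles →
prune → frequencies/F<sub>ST</sub> → distances/MDS → ancestry →
divergence screen → association → concordance):

```sh
pharmapop run-all --seed 17 --out-dir demo_run
```

prints the run summary

```
ancestry_mae_vs_truth   0.026330081993834707
concordance_accuracy    0.977
mean_fst                0.02892957662961468
n_pharma_oriented       100
n_pruned                2000
n_screened              19
```

meaning: estimated ancestry fractions recover the simulated truth to a
mean absolute error of 0.026; the discordance-injected re-call set
agrees with the truth genotypes at 97.7% (the default injected
discordance rate is 2.3%, emulating a validated allele-specific PCR
assay); the mean F<sub>ST</sub> between the two admixed cohorts is
0.029; all 2000 simulated (unlinked) variants survive LD pruning; and
19 of the 100 annotated pharmaSNPs pass the high-evidence E > 0.5
divergence screen. `demo_run/screen.tsv` ranks them, e.g.

```
id         gene     drug        ...  log2_ratio  delta   euclidean  direction
rs1001039  SLCO1B1  clopidogrel ...  1.9069      0.055   1.9077     Antioquia
rs1000340  CYP3A5   tacrolimus  ...  -1.8074     -0.100  1.8101     Choco
```

The same statistics on the published effect-allele frequencies are
available in `pharmapop.datasets`: for the tacrolimus-metabolism SNP
rs776746 (f = 0.81 in Antioquia vs 0.32 in Chocó) the package computes
Δ = 0.49, R = 1.3399, E = 1.4267, placing it at the top of the
Colombian pharmaSNP screen.

Every stage is also exposed as a library function
(`pharmapop.compute_fst`, `estimate_ancestry`, `divergence`,
`build_confusion`, ...) and as an individual CLI subcommand
(`simulate`, `freqs`, `fst`, `prune`, `dist`, `mds`, `ancestry
estimate`, `ancestry assoc`, `divergence`, `concordance`).

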