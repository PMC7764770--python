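# stockid

SNP-panel genetic stock identification for Arctic food fish, with
censored-contaminant statistics.

Subsistence fisheries in the Arctic need to know which fish carry
anthropogenic contaminants (Hg, As, PCBs), but chemical assays are
expensive and fish netted in the ocean are a mixture of stocks. If a
small panel of SNP markers can assign an individual back to its genetic
cluster of origin, contaminant testing can be targeted at the fish that
matter. This package implements both halves of that strategy for
salmonids such as Arctic char (*Salvelinus alpinus*):

1. **Assignment** — likelihood-based classification of individuals to
   candidate groups from biallelic SNP genotypes, validated by a
   replicated training/holdout protocol over ladders of F_ST-ranked
   marker panels (population level and fishing-site level).
2. **Contaminant statistics** — regression-on-order-statistics (ROS)
   imputation of left-censored non-detects, wet/dry-weight basis
   corrections, PCB congener aggregates and TCDD toxic equivalents,
   Aroclor-style congener fingerprints, guideline exceedances, and
   rank-based group comparisons (Kruskal–Wallis + Dunn, Spearman).

A Balding–Nichols genotype simulator and a log-normal contaminant
simulator generate fully synthetic datasets with the same statistical
structure, so the entire pipeline is testable without any deposited data.

## The model

**F_ST ranking.** For each locus, divergence between groups is estimated
with the Weir & Cockerham (1984) variance-components estimator computed
from genotype counts: with among-group, among-individual and
within-individual components *a*, *b*, *c*,

θ = a / (a + b + c),

and markers are ranked by θ computed **on the training half only**.

**Assignment likelihood.** Loci are treated as independent and in
Hardy–Weinberg proportions within each group. With smoothed training
frequency q̃ = (x + ½)/(n + 1) (x alt-allele count, n called alleles),
the log-likelihood of sample *i* in group *g* is

log L(i, g) = Σ_ℓ log P(d_iℓ | q̃_gℓ),  P(0) = (1−q̃)², P(1) = 2q̃(1−q̃), P(2) = q̃²,

summing over the sample's called panel loci; posteriors are the softmax
under equal priors and the sample is assigned to the argmax.

**Cross-validation protocol.** Per replicate (population mode): subsample
every group to the smallest group size; per iteration: split each group
50/50 into training/holdout, rank markers on training θ, assign holdout
at every rung of the panel ladder (2, 4, 8, …, all); 30 iterations × 3
replicates by default. Site mode keeps observed group sizes and a single
replicate.

## Worked example

```bash
python analysis/01_simulate_datasets.py
python analysis/02_population_assignment.py
```

The first script writes a synthetic two-cluster dataset at the reference
study shape (174 fish per cluster, 3055 SNPs, divergence F = 0.10, 2%
missing calls). The second runs the full replicated protocol and prints:

```
overall assignment accuracy by panel size:
      2 SNPs:  96.27%
      4 SNPs:  97.83%
      8 SNPs:  99.76%
     16 SNPs:  99.99%
     32 SNPs: 100.00%
     ...
   3055 SNPs: 100.00%

full-panel (3055 SNPs) pooled confusion matrix:
assigned_group  Northern  Southern
true_group
Northern            7830         0
Southern               0      7830
```

Reading: at this divergence a handful of top-F_ST SNPs already assigns
fish almost perfectly — accuracy exceeds 95% with 2 markers and
saturates by 16 — and the pooled confusion matrix at the full panel has
all mass on the diagonal (7830 = 87 holdout fish per cluster × 30
iterations × 3 replicates). `analysis/03_site_assignment.py` repeats the
experiment grouped by fishing site with very weak site divergence and
shows the opposite: accuracy stays far below useful levels at every
panel size. `analysis/04_contaminant_statistics.py` runs the contaminant
stage on a simulated 540-fish cohort (ROS completion, young/old and
geographic comparisons, PCB aggregates, exceedance counts).

The same stages are exposed as a CLI (`stockid simulate`, `stockid
assign`, `stockid contaminants`); every run writes a JSON manifest with
the seed and output checksums.

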