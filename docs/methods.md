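# Methods

This note documents the statistical models, the defaults and the design
choices behind `stockid`, and what the synthetic-data experiments do and
do not demonstrate.

## Genotype model and simulator

Genotypes are biallelic SNP dosages (0/1/2 alt alleles, with missing
calls) over independent loci. The simulator follows the Balding–Nichols
model: each locus draws an ancestral alt-allele frequency p uniformly
from (0.05, 0.95); each cluster draws its own frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F), which has mean p and variance p(1−p)F, so
the divergence parameter F is, in expectation, the F_ST the pipeline
later estimates. Genotypes are Binomial(2, frequency) draws; missing
calls are injected uniformly at random. Site-level structure is nested:
site frequencies are drawn around their cluster frequency with a
(typically much smaller) site-level F, reproducing strong cluster
divergence with weak differentiation among fishing sites.

Defaults are the reference study shape: 2 clusters × 174 samples, 3055
loci, F = 0.10. The choice F = 0.10 is the package's calibration of
"low-to-moderate divergence at which a few top-ranked SNPs assign
well"; with the ladder defaults it produces >90% accuracy from very
small panels, which is the regime the pipeline is designed to
demonstrate.

What the simulator does **not** reproduce: linkage between loci,
ascertainment bias of ddRAD SNP discovery, related individuals,
genotyping error correlated with depth, and locus-specific deviations
(selection). Passing tests therefore certify the estimators and the
protocol, not performance on any particular real dataset.

## F_ST estimation and marker ranking

Per-locus divergence uses the Weir & Cockerham (1984) genotypic
estimator: variance components a (among groups), b (among individuals
within groups) and c (within individuals, from observed heterozygosity),
with θ = a/(a+b+c). Negative estimates are retained as computed (ranking
needs only order); loci monomorphic across the groups considered are
flagged undefined and excluded from ranking. Ties in θ break by
ascending input locus index so rankings are reproducible.

Two numerical notes, both verified against an independently coded
brute-force implementation:

* the **unweighted mean of per-locus θ** is a ratio estimator and
  carries a downward Jensen bias (≈ −0.017 at F = 0.10 with 100
  samples/cluster and 2000 loci); the multi-locus ratio-of-averages
  Σa/Σ(a+b+c) recovers the generating F almost exactly. Both statistics
  are reported by the acceptance script.
* a locus needs ≥2 groups with called samples to be defined; groups with
  zero calls at a locus drop out of that locus's components.

The default panel ladder is 2, 4, 8, 16, 32, 64, 128, 200, 500, 1000,
2000 and "all defined loci"; rungs exceeding the defined-locus count
clamp to it. Panels are nested prefixes of one ranking.

## Assignment likelihood

The standard genetic-stock-identification likelihood: independent loci
in Hardy–Weinberg proportions within each candidate group, genotype
probabilities (1−q̃)², 2q̃(1−q̃), q̃² from the smoothed training
frequency q̃ = (x+½)/(n+1). The smoothing keeps q̃ strictly inside
(0, 1) so an allele unseen in training never yields −∞; with equal
priors the posterior is the softmax of the group log-likelihoods.
Missing calls are skipped; a sample with zero called panel loci is
flagged unassignable and excluded from accuracy numerators and
denominators. Exact likelihood ties assign to the first group in label
order and set an ambiguity flag.

No leave-one-out machinery is used: training and holdout are disjoint by
construction, which makes the likelihood unbiased for holdout samples
without it.

## Cross-validation protocol

Population mode, per replicate: every group is subsampled to the
smallest group size (removing size bias); per iteration each group is
split 50/50 into training and holdout — odd counts give the extra
sample to training — markers are ranked on the training half only, and
the holdout half is scored at every rung. Defaults: 30 iterations × 3
replicates. Site mode keeps observed group sizes, uses one replicate,
and excludes groups with fewer than 2 samples (warning). Optional
pre-imputation (below) is applied to the full dataset before splitting.

Randomness: one master seed; replicate r's subsampling stream is seeded
with the entropy tuple (seed, r, 0) and iteration i of replicate r with
(seed, r, i+1), so any single iteration is re-runnable in isolation and
every stage is byte-identical under a fixed seed.

**Null calibration is a dataset-level property.** Within one finite
dataset, repeated re-splitting does not estimate the population-level
accuracy: a group's training and holdout halves share the realised
group-level allele-frequency deviations of that finite sample, so at
zero divergence the within-dataset full-panel accuracy sits above ½
(≈0.55 at 100 samples/cluster and 500 loci) even though the marginal
accuracy over independent datasets is exactly ½. The calibration tests
therefore average over independent simulated datasets. The practical
reading: cross-validated accuracy on a single small baseline is an
optimistic estimate of how well truly new fish would be assigned, a
caveat that applies to real-data panels as much as to simulations.

## Missing-genotype imputation

Missing calls are imputed as Binomial(2, p̂) draws from the sample's own
group allele frequency at that locus (falling back to the overall
frequency, and left missing with a warning when neither exists).
Observed calls are never altered. This replaces tree-ensemble imputation
with the distributional equivalent under the package's own independence
assumptions; since assignment accuracy is insensitive to ≤10%
missingness either way (verified by the imputation-robustness test), the
simpler generative imputer preserves the analysis-relevant information.

## Censored contaminant statistics

**ROS.** Non-detects are left-censored at their detection limits.
Imputation follows Helsel-style log-normal regression on order
statistics: exceedance probabilities of the censoring thresholds via the
Hirsch–Stedinger recursion, plotting positions for detects and censored
observations, OLS of log(detected) on standard-normal quantiles, and
prediction at the censored plotting positions. Predictions exceeding
their own detection limit are clipped to it (with a warning). With fewer
than 3 detected values (or <2 distinct), the fit is unidentifiable and
the module substitutes limit/2 with a prominent warning. The procedure
is deterministic; the `seed` argument exists for interface uniformity.
ROS is exactly scale-equivariant, which the suite asserts at 1e-12.

**Basis corrections.** ww = dw × (1 − moisture); moisture is a fraction
in [0, 1), per-species means in practice. Round-trip error is bounded by
1e-12 in tests.

**PCB aggregates.** Total PCBs (Σ congeners), lipid-normalised total
(total / lipid fraction), DL-PCB toxic equivalents (Σ TEF-weighted
dioxin-like congeners), non-DL total, and the EU indicator sum PCB6
({28, 52, 101, 138, 153, 180}). TEFs default to the WHO 2005 mammalian
table; both the TEF mapping and the PCB6 set are plain dictionaries the
caller can replace — they are package defaults, not measured facts about
any particular dataset. The congener fingerprint flags a profile when ≥3
of the diagnostic congeners {110, 153, 118, 138} (the dominant peaks of
the legacy Aroclor 1254/1260 mixtures) sit among its top-5 peaks.

**Group comparisons.** Kruskal–Wallis with tie correction (H = 0, p = 1
when all values are identical — scipy raises there) plus Dunn-style
pairwise z statistics on mean ranks with tie-corrected variance,
two-sided and unadjusted. Spearman correlations are computed
pairwise-complete with ≥3 pairs per cell; constant variables flag as
undefined. Guideline exceedance converts values to the threshold's basis
first and uses a strict ">" — a value exactly at the guideline does not
exceed it.

**Contaminant simulator.** log concentration = log baseline + log
species effect + log region effect + age × slope + Normal(0, σ), with
defaults (σ = 0.8, slope = 0.05/yr, ages 5–30, species effects
char 1.0 / trout 4.0 / cisco 1.1 / whitefish 0.4, baselines Hg 0.03
mg/kg ww, As 4.0 mg/kg dw, total PCB 4 µg/kg ww) calibrated once so the
species means fall in the ranges typical of Arctic salmonid surveys
(char Hg near 0.07 mg/kg ww, lake trout several-fold higher and
dominating exceedances). A single shared species effect across analytes
is a deliberate simplification — real species × analyte interactions
(e.g. relatively higher Hg in whitefish) are not reproduced. Congener
profiles split a simulated total PCB burden by Dirichlet shares with the
diagnostic congeners up-weighted ~8×, so the fingerprint flag fires for
most fish by construction.

## Problem sizes in the test and acceptance runs

The suite exercises the full protocol at the reference shape (2 × 174
samples, 3055 loci, 3 replicates × 30 iterations × 12 panels — a few
seconds with the vectorised cumulative-likelihood evaluation) and uses
smaller shapes (20–100 samples/cluster, 100–2000 loci) for calibration
and oracle checks; the contaminant stage uses 540-fish cohorts and
n = 200 censored samples for ROS recovery. These sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances.

## Known limitations

* Independent-locus likelihood: linked markers would overweight shared
  signal; no LD pruning is provided.
* The group-frequency imputer and the HWE likelihood share assumptions;
  on strongly inbred or admixed data both degrade together.
* ROS assumes a single log-normal population; mixtures or heavy
  contamination of the lower tail bias the completed moments.
* Site-level assignment inherits all the weaknesses of tiny, unbalanced
  groups; accuracies for sites with a handful of fish are noisy and the
  protocol deliberately reports them per site rather than pooling.
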