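# Methods

This note records the models, estimators and numerical choices behind
`plastisel`, and what the synthetic-data tests do and do not establish.

## Synthetic data

**Genotypes.** The generator is the Balding–Nichols model. Each locus draws
an ancestral frequency p uniformly on a configurable interval (default
(0.1, 0.9), avoiding near-fixed loci that would be removed by the MAF filter
anyway). Population k's frequency is Beta(p(1−θ_k)/θ_k, (1−p)(1−θ_k)/θ_k),
so that E[p_k] = p and Var[p_k] = θ_k·p(1−p): θ is exactly the
variance-standardised divergence that Weir–Cockerham FST estimates, which is
what makes parameter-recovery tests well-defined. θ may be shared or
per-population (the per-population case is what the allele-matching β_i
estimator targets). θ = 0 returns the ancestral frequency exactly. Planted
"selected" loci use a separate, larger θ. Genotypes are drawn with
heterozygote probability 2p_k(1−p_k)(1−F) and homozygote probabilities
inflated by F·p_k(1−p_k); negative F (heterozygote excess) is allowed.
Microsatellites use the Dirichlet analogue (ancestral frequencies from a
symmetric Dirichlet; population frequencies Dirichlet(ancestral·(1−θ)/θ));
inbreeding is applied by making the two allele draws identical with
probability F. Missing calls are inserted independently at a configurable
rate. Loci are assigned to transcript clusters of fixed size; no linkage is
simulated beyond the cluster labels, so LD pruning on simulated data removes
essentially nothing — LD behaviour is tested with constructed correlated
fixtures instead.

**Expression.** Gene counts are negative binomial with mean
exp(baseline + effects)·library-factor and dispersion α (variance
μ + αμ²). Baselines are log-normal (natural-log mean 4.0, sd 1.5 —
typical bulk RNA-seq count magnitudes); the default dispersion is 0.1. The
design is the study's: two populations × three timepoints, 16 individuals
per population split 6/5/5 across timepoints. Exon counts are a multinomial
split of each gene's count with per-gene usage proportions (Dirichlet(5)),
so differential exon usage can be planted (an exon's usage proportion
switched in selected cells) without changing gene totals — usage and
abundance are decoupled by construction. Planted DGE adds a log2 fold change
to selected cells; planted GEV multiplies the dispersion there. Effect-size
defaults are config-exposed and not claimed to match any particular real
data set. One global seed expands to per-stage substreams so stages can be
re-run independently.

**What the simulations do not emulate:** read-level noise and mapping error,
genotype-calling error correlated with expression level, real LD structure,
correlated expression between genes, and batch effects. Passing tests
establish the estimators' behaviour under their generating assumptions, not
robustness to those artefacts.

## Genotype filters

The cascade order is quality → biallelic → MAF → missingness → HWE → LD;
each stage keeps a subset, and the cascade is idempotent. Genotype-quality
masking converts low-GQ calls to missing *before* allele frequencies and
missingness are computed (masking rather than site removal; sites failing
the downstream rules afterwards are dropped). Quality thresholds are strict
(QUAL > 30 kept), MAF and missingness inclusive (≥ 0.05 and ≤ 20 % kept).
The HWE test is the exact conditional test: conditioning on allele counts,
heterozygote counts of the observed parity are enumerated with weights
2^nAb·n!/(nAA!·nAb!·nab!), and the p-value sums configurations no more
probable than the observed one (computed in log-space; verified against a
rational-arithmetic enumeration oracle). The HWE filter keeps loci with
p ≥ 0.005, pooled across populations. LD pruning is a greedy left-to-right
pass within each transcript cluster: a locus is dropped when its
pairwise-complete squared Pearson correlation of dosages with any retained
locus of the same cluster strictly exceeds 0.20; zero-variance loci never
trigger removals; loci in different clusters are never compared. Two named
panels: "overall" (quality/MAF/missingness) and "neutral" (additionally
complete data, HWE, LD-pruned). Individuals are dropped at ≥ 3 missing loci
(the 20 % rule on a 19-locus panel) or via a pre-computed exclusion list
(e.g. full-siblings from external sibship inference, which is out of scope).

## Population-genetic estimators

H_S is Nei's sample-size-corrected gene diversity
ñ/(ñ−1)·(1 − Σp̂² − H_O/2ñ); F_IS = 1 − ΣH_O/ΣH_S as a ratio of sums over
loci (monomorphic loci contribute zero to both sums). The pairwise FST is
Weir–Cockerham (1984): variance components a (among populations), b (among
individuals within populations), c (within individuals), computed per allele
per locus from sample sizes, allele frequencies and heterozygote
frequencies, aggregated as ratio of sums Σa/Σ(a+b+c) over alleles and loci —
not the mean of per-locus ratios, which weights low-information loci
equally. Components are retained per locus for bootstrapping and for the
permutation scan. Multi-allelic loci contribute one term per allele, so
microsatellites flow through the same code. The population-specific FST is
the Weir–Goudet allele-matching β_i = (M_i − M_B)/(1 − M_B), where M_i is
the sample-size-corrected probability that two distinct allele copies drawn
within population i match and M_B the mean between-population matching
probability; matching proportions are averaged over loci before the ratio.
Under Balding–Nichols, E[M_i − M_B] = θ_i(1 − ΣP_a²), so β_i recovers the
per-population drift parameter — the basis of the recovery benchmarks.

Bootstrap CIs resample loci (not individuals) with replacement, re-aggregate
stored per-locus components, and take percentile quantiles; replicates where
the statistic is undefined are skipped and counted, with > 10 % skips an
error. The seed is an explicit argument everywhere.

PCA mean-imputes missing dosages, centres columns and does not scale
(variance-scaling would up-weight rare alleles); k-means reassignment runs
on the leading 75 PCs (clamped to availability) with 10 restarts, labels
ordered so cluster 1 is the largest.

## Outlier scans

The PC scan standardises dosages by the binomial sd √(2p̂(1−p̂)), takes K=2
left singular vectors, and regresses each SNP on them; because the score
vectors are orthonormal the per-component z-statistics are
β_k/√(RSS/(n−K)). The z-vectors are combined into Mahalanobis D² under a
minimum-covariance-determinant estimate (plain covariance for small panels),
rescaled by the genomic inflation factor λ = median(D²)/median(χ²_K), and
referred to χ²_K. "Varies along PC1" is operationalised as
argmax_k z_k² = 1. Zero-variance SNPs get p = 1.

The second, independent detector is a label-permutation scan of per-locus
WC θ̂ with empirical p = (1 + #{θ̂_perm ≥ θ̂_obs})/(n_perm + 1) — never
exactly zero, so BH is well-behaved. The permutation count bounds the
smallest achievable p at 1/(n_perm+1); with BH over L loci, joint outliers
are only detectable when n_perm is large relative to L/(number of true
outliers), which the pipeline defaults respect. This permutation scan
replaces a reversible-jump MCMC Bayesian FST method as the second detector:
it preserves the two-independent-methods intersection design while remaining
exactly testable at desk scale. A gene's retained selection value is the
*lowest* significant −log10 q among its joint outliers across both methods —
the least significant of the significant — matching the integration rule.

## Plasticity tests

**Normalization.** TMM with the standard constants: reference sample by
upper-quartile proximity, M/A double trimming (30 %/5 %, rank-based),
inverse-asymptotic-variance weights, factors scaled to geometric mean 1.
The implementation agrees with edgeR's `calcNormFactors` to ~1e-6 on
simulated matrices (cross-checked in the test suite). The expression filter
keeps a gene when every sample of at least one population × timepoint cell
has a nonzero count.

**DGE.** Per gene, an NB means model over the six cells with offset
log(library size × TMM factor). Dispersions are method-of-moments estimates
at Poisson-fitted means with a small-sample df correction, smoothed by
lowess on log mean count (trend only — gene-specific scatter is instead
absorbed by the quasi-likelihood dispersion). Cell means are fitted by
Fisher scoring on log m (the model is group-separable). Each of the nine
contrasts is tested by a quasi-likelihood F: the LRT drop from merging the
two cells, divided by a moderated Pearson dispersion
s²_mod = (d₀s₀² + df·s²)/(d₀+df) with d₀ = 10 and s₀² the median s², on
F(1, d₀+df). A plain χ² LRT is available via `use_ql=False`. This is a
simplified, documented stand-in for edgeR's Cox–Reid/empirical-Bayes QL
machinery; null simulations show type-I error within [0.03, 0.08] at
nominal 0.05. Fold changes are log2 ratios of fitted cell means moved to
the count scale of a typical library, with a prior count of 0.125.

**DEU.** Exon log2-CPM with 0.5/1 offsets. Precision weights come from a
lowess fit of √(residual SD) against mean log-count, evaluated at each
observation's fitted value and inverted (voom's construction). Exon usage is
isolated by subtracting each gene's per-sample precision-weighted average
log2-CPM: on this relative scale the gene-level expression variation —
which would otherwise dominate the exon residual variance — cancels, and
the weighted cell-mean contrast of an exon's relative values *is* the exon's
coefficient minus the weighted average coefficient of its gene's other
exons. The per-exon t uses the relative-scale residual variance with
df = n − (number of cells). Gene-level p combines the exon p-values by
Simes. Because the exon deviations within a gene sum to zero, they are
negatively dependent and the raw Simes statistic, while valid at any fixed
α, is not uniform over (0,1); its exact null depends only on the exon count
and residual df, so the statistic is referred to that null, computed once by
Monte Carlo (50 000 draws of studentised deviations, fixed internal seed)
and cached. Null multinomial-split simulations then give approximately
uniform gene p-values. Single-exon genes are excluded and logged.

**GEV.** Genes passing a > 1 count-per-million mean inclusion rule are fit
by maximum likelihood twice: full model with group-specific mean *and*
group-specific NB dispersion (with the log library×factor offset on the
mean; the model is separable by group, each group a 2-parameter fit by
alternating Fisher scoring on log mean and bisection on log dispersion),
and a reduced model with group means but one shared dispersion. The GEV
statistic is 2(ll_full − ll_reduced) on χ² with (groups − 1) df — i.e. the
test isolates the group effect on dispersion given group effects on the
mean, which is the reading adopted of the ambiguous "group factors omitted
from mean and overdispersion respectively" formulation; other contrasts can
be formed from the fitted models but are not exposed as defaults. The CV
filter removes genes whose fitted coefficient of variation,
√(dispersion + 1/mean) on the full model, lies outside (1e-3, 3), before
multiple-testing adjustment; this operationalises "CV of mRNA copy number"
via the NB mean-variance relation. Non-convergent fits (negative LRT) are
excluded and counted. At the study's per-group sample sizes the test has
limited power for moderate dispersion ratios — consistent with a real
analysis of this design finding no significant GEV genes — and the power
tests therefore plant strong (≥ 4×) dispersion shifts in well-expressed
genes.

## Integration

A gene is plastic when any DGE/DEU/GEV contrast reaches q < α (default
0.05), selection-flagged when it carries a joint-outlier SNP. Retained
values on both axes take the *lowest* −log10 q among the significant
results (a `retain="most_significant"` switch exists for sensitivity
analysis, off by default). The gene universe is the full transcript-cluster
list, not just expression-filtered genes, so "neither" genes are counted.
The 2×2 χ² uses the closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) without
Yates correction by default (the corrected variant is available; both give
the same qualitative answer on the worked example). A zero margin makes the
test undefined: the operation raises, and the pipeline records the counts
with a note instead of a statistic.

## Numerical and design notes

- Genotypes are stored as unordered allele-index pairs (int16, −1 missing)
  so biallelic and multi-allelic panels share one container and one
  F-statistic code path; biallelic panels expose a dosage view.
- WC components are computed only at loci where every population has at
  least one genotyped individual and the mean sample size exceeds 1; other
  loci propagate NaN and drop out of the ratio of sums.
- The NB log-likelihood floors μ at 1e-10 and α at 1e-10; dispersion MLE is
  bisection on log α in [−14, 6] with boundary detection.
- VCF is written as plain v4.2 text (GT:GQ, QUAL, cluster id as CHROM) and
  read back with cyvcf2; round-trips are bit-identical on calls, QUAL and
  GQ.
- Determinism: every stochastic function takes a seed; the simulators
  derive per-stage substreams from (seed, stage) so a stage can be re-run
  alone; identical config + seed reproduces byte-identical pipeline tables.

## Known limitations

- The DGE dispersion shrinkage and QL df are simplified relative to edgeR;
  on very small panels (< ~200 genes) the trend and s₀² estimates are
  noisy.
- The DEU Simes-null calibration assumes approximately normal studentised
  deviations; at extremely low exon counts the approximation degrades
  (full-distribution uniformity can wobble at the margins even though the
  α = 0.05 level remains close to nominal).
- The permutation-FST scan's resolution is limited by n_perm; q-value
  discreteness makes joint-outlier detection conservative on large panels
  with few permutations.
- The microsatellite FST recovery carries a small negative bias
  (≈ 5·10⁻⁴ at 19 loci) from the ratio-of-sums aggregation over few loci;
  it is well inside the benchmark tolerance.
- No LD is simulated beyond cluster labels; LD-pruning behaviour on real
  data with extensive intra-cluster correlation is exercised only by
  constructed fixtures.
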