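# Methods

This note documents the statistical machinery in `seapop`: the estimators,
the permutation schemes, the synthetic-data model used for validation, and
the places where a genuine design choice had to be made.

## Genotype container and filters

Genotypes are alt-allele dosages (0/1/2) with a reserved missing sentinel;
dosages are never implicitly imputed. The SNP filters run in a fixed order
and each step is logged with before/after counts:

1. **Call rate** ≥ `call_rate` (default 0.80) in at least S−1 of S sites.
   The "all but one site" rule tolerates a single badly genotyped site
   without discarding a marker informative everywhere else.
2. **Read depth** ≥ 5. Granularity is configurable: the default sets
   individual low-depth calls to missing (heterozygotes cannot be called
   reliably from fewer reads); a per-SNP-mean mode drops whole markers.
   The step is skipped when the input carries no depth information.
3. **MAF**: global ≥ 0.01 **or** local (any single site) ≥ 0.05. The OR
   keeps alleles that are rare globally but common somewhere — exactly the
   markers informative about local structure — while removing putative
   sequencing errors.
4. **Heterozygosity** ≤ 0.6 in ≥ S−1 sites, a guard against collapsed
   paralogs, which masquerade as permanently heterozygous SNPs.
5. **Individual missingness** ≤ 12%.
6. Duplicate (chromosome, position) records dropped; optionally one SNP
   per locus (the max-MAF one) for panels with multiple SNPs per RAD tag.

LD pruning computes composite (dosage) r² pairwise-complete within each
chromosome — phase is unknown, so gametic LD is not attempted — and removes
one random member of each offending pair until none remains; pairs sharing
members therefore cost fewer removals than there are pairs.

The identity-by-missingness diagnostic is a classical metric MDS of the
missingness-mismatch distance between individuals: batch effects appear as
clusters where biology should play no role.

## Weir–Cockerham θ

Per locus and population we take the genotyped sample size n, alt frequency
p and observed heterozygosity h, and evaluate the 1984 variance components
a (among populations), b (among individuals within populations) and c
(within individuals). The multi-locus estimator is the ratio of sums
Σa / Σ(a+b+c), which weights loci by their information content. Negative
estimates are reported as-is — truncation would distort the bootstrap
distribution — and only clamped at zero where a distance is required
(UPGMA). Pairwise CIs are percentile bootstrap over loci (the toolchain
convention; BCa is not implemented), with a one-sided p equal to the
fraction of replicates ≤ 0, floored at 1/(n_boot+1), and BH-FDR across
pairs. Pairs whose 95% CI includes zero are merged (transitively) into
imputation groups.

## Diversity

H<sub>o</sub> and H<sub>e</sub> (with the 2n/(2n−1) small-sample
correction) are averaged over loci polymorphic within the site;
monomorphic/polymorphic counts are reported alongside. F<sub>IS</sub> is
the within-population ratio form 1 − ΣH<sub>o,l</sub>/ΣH<sub>e,l</sub>.
Its interval is built by re-pairing alleles among individuals within the
site (a Hardy–Weinberg permutation null) and re-centring the permutation
spread on the point estimate; the source toolchains do not document their
interval construction, so this choice is ours and is labelled as such.
Nucleotide diversity divides the mean per-locus average pairwise
difference (equal to unbiased H<sub>e</sub> for a biallelic SNP) by a
90-bp locus length, the read length typical of the motivating data.

## AMOVA

The hierarchical AMOVA (groups / populations / within populations) uses
squared Euclidean distances between **allele rows** — each individual
contributes its two alleles as separate rows; since the sums of squares
depend only on per-locus allele counts within each stratum, the arbitrary
pairing of alleles across loci is irrelevant. This keeps F<sub>CT</sub> and
F<sub>SC</sub> on the gene-level scale of standard F-statistics: a
dosage-vector AMOVA would estimate ≈ 2F/(1+F) for a true divergence F,
because the among-group variance of dosage means scales with 4·Var(p)
while the within-population dosage variance is only 2pq. Missing loci are
handled pairwise-complete with rescaling to the full locus count.
Permutation p-values move whole populations among groups (F<sub>CT</sub>)
and individuals among populations within groups (F<sub>SC</sub>), with
p = (1 + hits)/(n_perm + 1).

## Mantel isolation-by-distance

Mantel r between the off-diagonal θ and distance vectors; one-sided p from
joint row/column permutations of the distance matrix (the literal identity
draw is skipped so a perfect association attains the minimal p). An OLS of
θ on distance supplies the Ezekiel-adjusted R², optionally after
θ/(1−θ) linearization.

## Imputation, UPGMA, DAPC

Missing dosages are drawn from the empirical genotype-class frequencies of
the locus within the individual's CI-defined group (global fallback),
seeded. The draw preserves group allele and genotype frequencies in
expectation, which is what every downstream frequency-based statistic
consumes; model-based imputers would add dependencies without changing
those expectations.

UPGMA runs on θ clamped at zero, with sites pre-sorted lexicographically so
ties resolve deterministically. A pair at distance d joins at height d/2.
Bootstrap support of an internal node is the percentage of locus-resample
trees containing the same leaf cluster; tree fit is
R² = 1 − SS(coph − d)/SS(d − d̄).

DAPC: dosages are centred (mean-filled where missing), reduced by PCA, and
clustered by k-means for K = 1..max_k with
BIC(K) = n·ln(WSS/n) + K·ln(n). For the cluster search **all** PCs are
retained by default: concentrating on a few leading PCs concentrates noise
along them and biases the WSS decline toward spurious clusters, whereas
with the full spectrum the ln(n) penalty correctly prefers K = 1 for
panmictic data. The supervised step is an LDA with equal priors on the
retained PCs; when the PC count is unset it is chosen by the α-score
(mean over groups of leave-one-out reassignment rate − 1/K), which peaks
at an interior PC count because excess PCs overfit the discriminants.

## Spatial eigenfunctions

dbMEMs follow the PCNM construction: distances above the truncation t
(default: longest MST edge, the smallest t keeping the site graph
connected) are replaced by 4t, the matrix is Gower-centred and
eigen-decomposed, and positive-eigenvalue axes are returned orthonormal
with a deterministic sign. With t ≥ max distance this reduces exactly to
classical PCoA. The stricter positive-Moran's-I screening is available
behind a flag. Marine least-cost distances are accepted as a user TSV;
no GIS computation is attempted.

## RDA and permutation tests

`rda_fit` centres (optionally scales) the response, residualizes response
and predictors on any conditioning matrix, computes fitted values through a
rank-revealing least-squares solve, and eigen-decomposes them; eigenvalues
are reported on the per-(n−1) scale and match R vegan's `rda` to numerical
precision on test instances (partial models match vegan's constrained
eigenvalues as well; our partial adjusted R² uses Ezekiel's formula with
rank-based df, slightly different from vegan's semipartial convention —
variance partitioning works with adjusted-R² *differences*, where the two
agree). SNP "loadings" are Pearson correlations of response columns with
axis scores.

Permutation ANOVA: rows of the (reduced-model residualized) response are
permuted; marginal tests residualize the term on all other terms, judging
the term's rank against its own scale so a duplicated predictor is
correctly rank-0 (p = 1); per-axis tests condition on the preceding
canonical axes. Variable screening runs |r| ≥ 0.7 greedy pruning (drop the
member of the strongest pair with the higher mean |r|, later column on
ties), single-variable permutation ANOVA at p ≤ 0.1, then an iterative
VIF < 10 filter. `ordistep` alternates forward inclusion (best marginal
p ≤ 0.05, F as tie-break) and backward elimination (marginal p > 0.1).
Variance partitioning reports [env-unique], [joint], [spatial-unique] and
residual as differences of adjusted R², so the four fractions close to 1
exactly; the unique fractions are tested on the conditioned models.

The response unit is configurable everywhere: site × allele-frequency
(13 rows at study scale; used for the structure RDAs) or individual ×
dosage (used for the GEA, whose loading-outlier rule needs per-SNP
variation across individuals).

## GEA outliers and polygenic scores

Candidates are SNPs whose loading on a permutation-significant axis lies
≥ 3 SD from that axis's mean loading (≈ 0.27% two-sided tail under
Gaussian loadings); a SNP flagged on several axes keeps the largest-|z|
axis. Each candidate is assigned to the environmental variable maximizing
|Pearson r| with its dosage (ties to the earlier column). The polygenic
score per variable sums the candidates' dosages after orienting each SNP
so its dosage increases with the variable (per-SNP OLS slope; zero slope
keeps the original coding) — the score~variable regression therefore
always has a non-negative slope, and negating a variable reflects scores
to 2k − s while leaving the fit statistics unchanged. Score against
variable is fitted linear and quadratic; AIC = n·ln(RSS/n) + 2k (Gaussian
form, constants cancel) picks the model. Variables backed by fewer than
3 candidates are flagged low-support.

## Assignment and migrant detection

Assignment follows the leave-one-out frequency approach: per reference
unit, alt-allele frequencies are computed with the focal individual's
alleles removed from its home unit; genotype likelihoods are
Hardy–Weinberg (p², 2pq, q²) in log10, summed over called loci, with zero
frequencies floored at 1/(2N+2). The home-likelihood migrant test draws,
for each Monte-Carlo replicate and locus, two alleles without replacement
from the unit's observed allele pool and evaluates the resulting genotype
under its own leave-those-alleles-out frequencies — the identical
procedure applied to real members, making resident p-values uniform by
exchangeability. (A null simulated from the point-estimate frequencies is
markedly anticonservative at realistic sample sizes, because the observed
leave-one-out likelihood carries a Kullback–Leibler penalty per locus that
the simulated genotypes do not.) Balanced assignment repeats the
leave-one-out run on equal-size subsamples to remove the attraction of
large reference units. Assignment always uses the full panel — never
markers pre-selected for differentiation — to avoid high-grading bias.

## Synthetic data model

Sites sit at random positions along a 1-D coastline (default 300 km)
mapped to latitude/longitude; clusters are contiguous blocks of sites.
Environmental variables are Gaussian-process draws with exponential
covariance (default range 100 km). Neutral allele frequencies follow a
two-level Balding–Nichols hierarchy: cluster frequencies Beta-distributed
around an ancestral Uniform(0.05, 0.95) frequency with divergence
F_between (default 0.006), site frequencies around cluster frequencies
with F_within (default 0.003). With six clusters over thirteen sites these
defaults put the neutral mean pairwise θ near 0.009, the differentiation
level of the motivating system. Adaptive loci replace drift with a
logistic cline: site frequency = logistic(logit(p_anc) + β·z) with z the
standardized value of the locus's round-robin-assigned variable and β the
effect slope (default 2). Genotypes are Binomial(2, site frequency);
missingness is MCAR at 4.7% by default, with an optional site-biased mode
for exercising the IBM diagnostic. Everything derives from a single seed;
identical seeds give byte-identical files.

What the generator does **not** emulate: linkage between loci, sweepstakes
reproductive success / within-site heterozygote deficits (simulated sites
are at Hardy–Weinberg, so F<sub>IS</sub> centres on zero rather than the
~0.2 typical of bivalves), marine least-cost geometry, and genotyping
error beyond MCAR missingness. Passing tests therefore demonstrate
estimator correctness and calibration under a clean model of the study
design, not robustness to those real-data features.

## Problem sizes and numerical choices

The packaged validation suite and the acceptance script run at desk scale,
chosen as the smallest sizes at which the targeted properties are sharp:
FST recovery at 13 sites × 35 × 2,000 loci over 20 seeds; null calibration
of the RDA/AMOVA/Mantel/migrant permutation tests over 200 seeds of small
panels; GEA operating characteristics at 50 × 5,000 Gaussian loadings and
a 13 × 20 × 820-SNP planted-cline panel; the full acceptance pipeline at
13 × 35 × 2,060 SNPs with 500-replicate bootstraps and 999-replicate
Monte-Carlo nulls. Permutation p-values are always (1 + hits)/(n + 1).
Eigen-decompositions fix signs by the largest-magnitude-loading-positive
rule; UPGMA ties break lexicographically; degenerate inputs (empty panels,
all-zero distances, loci with no calls) raise informative errors rather
than propagating NaNs.

## Known limitations

- The F<sub>IS</sub> interval construction is a package choice (see above).
- The sequential axis test uses the simple preceding-axes conditioning
  scheme; for strongly collinear predictors more elaborate schemes exist.
- Bootstrap CIs are percentile, not BCa; very asymmetric per-locus
  component distributions could shift coverage slightly.
- The migrant test's exchangeable null assumes within-unit Hardy–Weinberg
  pairing of alleles, as does the likelihood itself.
- GIS-based marine distances and genome-scan outlier detection are
  consumed as inputs, never computed.
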