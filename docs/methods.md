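# Methods

`admixkit` re-implements, as a single testable library, the analysis chain
used to characterise admixed, consanguineous cohorts genotyped on SNP
arrays: genotype QC, ancestry inference, runs of homozygosity, uniparental
diversity, haplotype-based selection scans, loss-of-function (LOF)
frequency analysis, and weighted-LD admixture dating.  Every stage is
validated against a synthetic-cohort generator with known ground truth, so
the full pipeline runs and is tested without any external data.

## Synthetic cohorts (`synthgen`)

**Model.** K ancestral populations carry allele frequencies drawn from the
Balding–Nichols model: `P[k,l] ~ Beta` with mean `p0[l]` and variance
`F[k]·p0[l]·(1−p0[l])`, where `p0 ~ Uniform(0.05, 0.95)` keeps sites away
from fixation (sites may still drift monomorphic in a sampled cohort, and
downstream code must tolerate that).  Individual ancestry proportions Q are
supplied by the caller; haplotypes are painted as mosaics whose breakpoints
follow a Poisson process at rate `g` per Morgan — the signature of a single
admixture pulse `g` generations ago — with each segment's ancestry drawn
iid from the individual's Q row, and each allele drawn
`Bernoulli(P[ancestry, l])`.  Allele 1 is the derived allele throughout.
Two-pulse cohorts mix two painted layers: a background painted at the old
rate is overwritten, in segments painted at the recent rate, by the recent
source with the recent admixture fraction; the resulting ancestry
covariance decays as a sum of the two exponentials, which is what the
dating module fits.

**Choices.** Balding–Nichols rather than a coalescent simulator because it
is the generative model the admixture estimator assumes, runs in
milliseconds, and yields closed-form checks (frequency conservation, Beta
moments, exponential tract lengths).  The cost is realism: sites are
independent within an ancestry tract, so there is no background LD, no
mutation process and no allele-frequency spectrum shaped by genealogy.
Passing tests therefore demonstrate correctness of the estimators under
their own model assumptions, not robustness to background LD — the main
caveat when carrying conclusions to real array data (for the selection
scan especially, real neutral nSL distributions are wider than the
simulated ones; the frequency-bin standardization absorbs part but not all
of that difference).

Consanguinity is emulated by copying one haplotype over the other inside a
requested interval (`inject_roh`), which makes the injected region exactly
autozygous and is idempotent.  Deleteriousness-linked frequencies multiply
the derived-allele frequency of LOF variant l in population k by
`exp(−strength[k]·score_l/50)`: a crude but monotone stand-in for
mutation–selection balance in which a larger `strength` plays the role of a
larger effective population size (more efficient purifying selection).

In the test suite, cluster-structured cohorts draw Q rows from
Dirichlet(0.3): most individuals strongly anchored to one ancestry with an
admixed minority, the regime structured human cohorts show and in which the
unsupervised admixture model is well identified.  Recovery tests use a
20-Morgan, 10-chromosome map so each individual carries enough ancestry
tracts that its realized genome ancestry matches its drawn Q (with 2
Morgans the realized fraction alone deviates from Q by ~0.05, which would
dominate the estimator's error).

## QC (`qc`)

Four filters, applied in this order: relatedness pruning, site
heterozygosity outliers, call rate (sites before samples, both with strict
inequalities at the thresholds: site missingness > 0.01, sample > 0.05),
and the Hardy–Weinberg exact test at p < 1e-6.  The heterozygosity rule is
one-sided (rate > mean + 3 SD) because only excess heterozygosity marks a
badly clustering assay.  The HWE test is the exact conditional test (sum of
heterozygote-count probabilities not exceeding that of the observed count),
evaluated with the standard recurrence and cross-checked in the tests
against full enumeration for every table with up to 50 individuals.
Relatedness uses the method-of-moments IBD decomposition from observed
IBS counts and HWE expectations (PI_HAT = P(IBD=2) + P(IBD=1)/2, default
threshold 0.185, the midpoint between 2nd- and 3rd-degree expectations);
the finite-sample correction factors some implementations apply to the
expected-IBS terms are omitted, which is immaterial at the cohort sizes
used here but makes the estimator mildly biased for very small N.  Note the
estimator assumes a homogeneous population: in structured cohorts,
same-cluster pairs show inflated PI_HAT, so a handful of removals on clean
structured data is expected behaviour, not a bug.

## Ancestry structure (`structure`)

- **LD pruning**: greedy sliding-window r² pruning (window 200 SNPs, step
  50, r² > 0.4 removes the lower-MAF member, tie broken toward the later
  position), iterated until stable.
- **PCA**: genotypes centred by 2p̂ and scaled by `sqrt(2p̂(1−p̂))`
  (Patterson scaling), monomorphic sites excluded, SVD of the scaled
  matrix; projection multiplies new scaled genotypes onto the stored
  loadings with the training-set frequencies.  Scores are sign-arbitrary.
- **Gaussian clustering**: EM mixtures on the first 6 PCs over four
  covariance families (spherical, diagonal, shared-full, full — spanning
  the constrained-to-flexible spectrum), K selected by BIC with 20
  k-means++ restarts per fit.  Fits with an empty or singleton component,
  or a covariance collapsed onto the regularization floor, are excluded
  from selection: these are the spurious high-likelihood solutions of
  unconstrained mixture EM, and excluding them is what makes BIC selection
  reliable here.
- **Admixture estimation**: the standard binomial likelihood
  `l = Σ_il [g_il ln Σ_k q_ik p_kl + (2−g_il) ln Σ_k q_ik (1−p_kl)]`,
  maximised by plain EM (multiplicative updates for Q and P from the same
  E-step).  P is clamped to [1e-6, 1−1e-6]; missing entries are skipped
  per-entry rather than imputed; the log-likelihood is non-decreasing up to
  the clamp and iteration stops at relative change < 1e-6.  Plain EM needs
  a few hundred iterations where quasi-Newton acceleration would need tens;
  at desk scale this costs seconds and keeps the monotonicity property
  testable.
- **Cross-validation**: per fold, a random 10 % of observed genotype
  entries is masked, the model refitted, and the masked entries scored by
  mean binomial deviance against the fitted dosage 2·(Q̂P̂); the K with the
  lowest mean error over folds is selected.
- **Q dendrogram**: Euclidean distances between Q rows (the distance is
  configurable; Euclidean is the default recorded in the run report),
  average-linkage (UPGMA) agglomeration, newick export with optional
  cluster and ROH annotations on the leaves.

## Runs of homozygosity (`roh`)

The scanning-window heuristic with the standard array defaults, all
exposed in `ROHParams`: 50-SNP windows are called homozygous when they
contain at most 1 heterozygote and 5 missing calls; a SNP is in-run when at
least 5 % of the windows overlapping it (only windows fully inside the
chromosome are counted) are homozygous; maximal in-run stretches are split
at gaps > 1 Mb and reported when they span ≥ 100 SNPs and ≥ 1 Mb at ≥ 1
SNP per 50 kb.  Detection is label-free (invariant to allele flips).
`F_ROH` divides total ROH Mb by a genome length that defaults to the span
of the variant table.  The `--het`-style inbreeding coefficient is
`F = (O_hom − E_hom)/(L_used − E_hom)` with
`E_hom = Σ_l [1 − 2p̂_l(1−p̂_l)·n_l/(n_l−1)]`, n_l the observed allele
count at site l.

Note the boundary interaction: a tract of exactly the minimum SNP count is
recovered or missed depending on how it aligns with the marker grid, so
recovery guarantees in the tests use tracts comfortably above the minima
(2.5 Mb at 20-kb spacing).

## Uniparental diversity (`uniparental`)

Nei's bias-corrected haplotype diversity `H = n/(n−1)(1 − Σ p_i²)`.  The
Y/mt ratio is reported at full precision and truncated (not rounded) to two
decimals, because published two-decimal ratios of this kind are reproduced
by truncation (0.574/0.873 = 0.6575… prints as 0.65); which convention a
given paper used is rarely stated, so both values are returned.

## Selection scan (`selection`)

nSL compares mean pairwise haplotype-identity tract lengths, in SNP units,
between derived and ancestral carriers of a focal SNP.  The tract of pair
(i, j) at focal x is defined here as the number of SNPs in the maximal
contiguous SNP interval containing x over which i and j agree at every SNP
— so L ≥ 1 always, intervals truncate at chromosome ends without penalty,
and no genetic map is needed.  `nsl_raw = ln(SL_A/SL_D)`; a sweep on the
derived allele drives it negative.  A SNP is scored only when MAF ≥ 0.05
and both carrier classes hold ≥ 2 haplotypes.  The production scan derives
all tract lengths for a pair at once from previous/next-mismatch arrays;
the test suite carries an independent brute-force oracle that expands
left/right per focal SNP and requires exact equality on 100 seeded
instances.

Standardization bins scores by derived-allele frequency (50 equal-width
bins by default; bins with < 2 variants merge into the nearest occupied
neighbour; zero-variance bins flag their scores rather than dropping them)
and z-scores within bins.  Candidates must satisfy |nsl_std| ≥ 2 **and**
|nsl_std| at or above the cluster's 99th percentile **and** carry a trait
annotation.  The percentile defaults to 99 with 99.9 available — the two
conventions in circulation for this style of scan; the default follows the
less stringent one and the choice is recorded in the run report.  The
shared/private partition assigns every candidate to one cell of the
inclusion/exclusion lattice over clusters; cell counts sum to the union.

## LOF analysis (`lof`)

The LOF set is the union of a curated list and all stop-gained variants
present in the genotype data.  Differentiation is tested one-vs-rest per
variant and cluster with the 1-df allelic chi-square on 2×2 allele counts
(no continuity correction), Bonferroni-controlled over variants × clusters
(the conservative family; variants-only is available).  Monomorphic
variants get p = 1 and a flag.  The deleteriousness ratio divides the
median allele frequency of high-scoring LOFs (score ≥ 25) by that of
low-scoring ones (≤ 5) within each cluster; mid-range scores are excluded,
so the statistic is invariant to them, and empty bins or a zero low-bin
median are flagged rather than dropped.  A genotype × cluster contingency
chi-square (with a low-expected-count warning) replaces tree-based
visualisations of genotype-by-ancestry structure.

## Admixture dating (`dating`)

Weights are the reference allele-frequency differences
`w_l = ref1_l − ref2_l`; for every same-chromosome pair with
0.5 cM ≤ |Δ cM| ≤ 30 cM (dmin excludes background LD; both ends
configurable), the haplotype covariance `D_lm = f_11 − p_l p_m` in the
target is accumulated as `D·w_l·w_m` into 0.1-cM distance bins.  The curve
is invariant to swapping the references and to rescaling the weights (the
amplitude absorbs it).  Fitting is nonlinear least squares of
`a·exp(−g·d) + c` (d in Morgans, so g is directly generations since the
pulse) with multistart over log-spaced g; the two-pulse model
`a1·exp(−g1 d) + a2·exp(−g2 d) + c` (g1 > g2 enforced by parametrization)
is accepted only when a nested F-test on residual variance rejects at
α = 0.05.  Standard errors are leave-one-chromosome-out jackknife when ≥ 2
chromosomes contribute.  A slow pulse (small g) is nearly collinear with
the affine term over a 30-cM window, so two-pulse fixtures in the tests
extend the window to 60 cM; the same applies to real curves when a recent
event is suspected.  Calendar conversion is
`year = ref_year − g·gen_time_years` (defaults 30 years and 2000 CE,
exposed because published baselines vary and are rarely stated).

## Problem sizes and determinism

Every stochastic test and simulation is seeded and reproducible
bit-for-bit.  Suite sizes were chosen as the smallest that make the checks
sharp: admixture recovery at N=200, L=5000, K=3, F=0.2 on a 20-Morgan map;
cross-validation at N=150, L=2000 over K=1..5; dating at 4×1-Morgan
chromosomes, 1200–1600 variants, 200–250 diploids; ROH recovery on 20
seeded 50-Mb fixtures; the null calibration of the Bonferroni procedure at
2000 replicates of 97 variants × 4 clusters; nSL oracle equivalence on 100
instances up to 50 haplotypes × 200 SNPs.

## Known limitations

- No background LD in the generator; selection-scan calibration on real
  data needs genome-wide empirical standardization, as here, but tails will
  be heavier.
- The admixture EM is unaccelerated; for cohorts beyond a few thousand
  samples × 100k sites a quasi-Newton or SQP accelerator would be needed.
- PI_HAT assumes homogeneity; run relatedness pruning with structure in
  mind (or on within-cluster subsets) for strongly structured cohorts.
- The weighted-LD estimator uses phased haplotype frequencies; an unphased
  covariance estimator is out of scope.
- Haplogroup assignment, IBD-segment calling and effective-population-size
  reconstruction are out of scope; their outputs can be consumed as
  precomputed inputs where needed.
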