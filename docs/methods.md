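# Methods

This note documents the statistical procedures implemented in `milispread`,
the synthetic-data model behind its tests, the defaults and why they were
chosen, and what the package deliberately does not do.

## Normalization

Raw read counts are transformed to log-CPM,
`log2((count + 0.5)/(library reads/10^6))`, where library size is the total
read count of the sample at matrix construction and is carried unchanged
through feature filtering (CPM always refers to full library depth). The
read-support filter keeps features with strictly more than `threshold`
(default 100) reads summed over all samples and is applied to raw counts
*before* normalization, so that the normalized analysis set equals the
filtered set. Cyclic loess runs pairwise: for each ordered sample pair an
M-vs-A lowess trend (span 0.7, 2 robustness iterations) is estimated and
half is subtracted from one sample and added to the other; the sweep over
all pairs is repeated 3 cycles. Both span and cycles are arguments. Because
each adjustment is an equal-and-opposite ±trend/2, the per-feature mean over
samples is conserved exactly. IsomiR collapsing sums raw counts within
user-supplied groups; the sequence-similarity rule that defines those groups
is a caller concern (sequence handling is out of scope here).

## Differential expression

Each feature is fitted by ordinary least squares,
`expression ~ intercept + group (+ confounder dummies)`, on the normalized
log scale; the reported statistic is the t-value of the group coefficient
with n − p residual degrees of freedom. With no confounder this reduces
exactly to the pooled-variance two-sample t-test (verified against an
independent implementation in tests). OLS was chosen over moderated
(empirical-Bayes) variance because it is fully specifiable and exactly
testable; with a few hundred retained features and log-scale data it is an
adequate engine for the set-level analyses that consume these statistics.
Significance convention: two-sided p, Benjamini–Hochberg FDR < 5%.

The tissue origin of each sample (P/M vs A/S) is entered as a categorical
confounder when ascitic and solid samples are analyzed together. Note that
samples of one patient are correlated (see the generator below); the
per-feature model treats samples as exchangeable given the confounder, so
strictly valid null calibration holds when one sample per patient enters a
comparison — the package's own null-calibration test uses the primary (P)
samples for exactly this reason.

## Gene-miR sets

A gene set is coupled with its **miR set** — the miRNAs whose verified
targets are over-represented in the set. For each miRNA the 2×2 table
(in-set targeted / in-set non-targeted vs out-of-set targeted / out-of-set
non-targeted) is tested with a one-sided Fisher's exact test; the enrichment
tail is the upper hypergeometric tail P(X ≥ k) with X ~ Hypergeom(N, K, n).
miRNAs with p < 0.05 form the miR set. Two readings of the background
("all genes" including or excluding the gene set) produce the *same* 2×2
table and therefore the same Fisher p-value, so no configuration switch is
needed. The gene universe defaults to genes present in both the target table
and the expression analysis — the analyzed transcriptome is the defensible
"all genes".

Set-level deregulation uses a competitive permutation test: the observed
score is the mean member t-statistic and the null draws equally sized random
feature sets (without replacement) from all scored features; the two-sided
p-value uses the add-one estimator around the null mean, with float-level
ties counted as extreme. A score of exactly zero is labeled "up" (fixed,
arbitrary convention). Gene- and miR-half p-values are combined with
Fisher's method (−2(ln p_g + ln p_m) on χ² with 4 df; zero p-values are
clipped at 1e-300 with a warning), and combined p-values are BH-corrected
across all sets of one comparison. Concordance curves report, along a
significance-cutoff grid, the percentage of significant sets whose halves
move in opposite directions and — within that inversely deregulated subset —
the percentage with the gene set down and the miR set up; empty strata are
reported as missing, never as zero.

## ceRNA network statistics

- circRNA index = back-splice events / (back-splice + linear splice events),
  per sample. "Events" are read counts supporting the junctions.
- lncRNA/coding ratio = median lncRNA expression / median coding expression,
  with medians taken on the linear scale (2^log-expression) so the quantity
  reads as an abundance ratio; a flag switches to log-scale medians.
- miRNA totals normalized to snRNA or snoRNA totals (raw counts), and the
  miRNA/long-RNA ratio with long linear RNA = coding + lncRNA. The two
  normalizers cancel algebraically in the miRNA/long-RNA ratio; both columns
  are still reported for symmetry with the boxplot layout they feed.
- Spread-type comparisons of per-sample statistics use the two-sample
  Student's t-test (pooled variance). The per-gene analysis averages
  expression over the samples of one tissue class (solid = P+M,
  ascites = A+S) and spread type and compares non-miliary minus miliary
  means per biotype with a paired t-test across genes; the pairing is the
  gene, for which no distributional choice is needed beyond normality of
  mean differences at a few hundred genes.

## The 13 sRNA spread predictor

`score = median(expr[3 miliary-up sRNAs]) − median(expr[10 non-miliary-up
sRNAs])`, computed per sample on consistently normalized log expression
(or −ΔCq, which is order-isomorphic). The score is location-invariant and
member-order-invariant. Calls come from a cohort-median split: strictly
above the median → miliary; at or below → non-miliary (ties deliberately
fall to non-miliary; the convention is arbitrary but fixed). All-identical
scores are refused.

Signature selection is intentionally not model-driven: members are the
sRNAs significant (FDR < 5%) in the miliary-vs-non-miliary comparison
restricted to primary ovarian (P) samples and not significant in *any* other
supplied comparison (metastatic or ascitic), partitioned by direction.
Selection refuses to build a signature with fewer than two members per
direction. The shipped default signature carries the 13 published member
identifiers (3 miliary-up, 10 non-miliary-up).

## Survival analysis

Cox proportional-hazards models are fitted by maximizing the Breslow
partial likelihood (statsmodels `PHReg`, `ties="breslow"`); the coefficient
covariance is the inverse observed information and confidence intervals are
Wald. Breslow is the single supported tie-handling method — it is the
simplest exactly specifiable choice, and the test suite validates the fitted
optimum against a brute-force grid maximization of the Breslow partial
likelihood on small single-covariate datasets. Monotone partial likelihoods
(a covariate that perfectly separates events) are detected via
non-convergence or runaway coefficient/SE magnitudes and raised as errors.
FIGO stage is coded ordinally (II/III/IV → 0/1/2) so one coefficient carries
the stage trend; residual tumor, grade (3 vs 2) and the median-dichotomized
spread predictor are binary; age is in decades.

Transfer validation: the training model's linear predictor
`Σ βⱼ xⱼ` (no baseline hazard needed) is computed for every validation
subject and entered as the single covariate of a new Cox fit on the
validation survival data. The calibration slope should be 1 when the
transferred risk ordering and scale hold; validation passes when the 95% CI
of the slope covers 1. A second check asks whether a covariate's validation
hazard ratio falls inside the training model's 95% HR interval.

## Synthetic cohort generator

The generator emulates the data structure the pipeline assumes, with every
planted effect echoed in the output for recovery testing.

**Layout.** Default 23 patients, 11 miliary : 12 non-miliary, four tissue
origins each (P, M, A, S) → 92 samples. Feature counts default to 1200
coding, 300 lncRNA, 150 miRNA, 80 piRNA, 20 snRNA, 20 snoRNA — a deliberate
desk-scale reduction of a real transcriptome that preserves the *relative*
mass of the biotypes (coding RNA dominates; planted miRNA targets are a
small fraction of coding mass). The 13 default signature identifiers are
injected verbatim as features so the shipped signature applies directly to
generated cohorts.

**Counts.** Per-feature baseline log2 abundances are biotype-specific
(snRNA/snoRNA high, lncRNA low) with N(0, 1.5) per-feature scatter. Each
patient carries per-feature log-normal random intercepts (log2 SD 0.25)
shared by all of that patient's samples — ascitic and solid samples of one
patient are correlated, which is why tissue origin is a confounder and not a
blocking factor downstream. Relative abundances are renormalized per sample
(compositional, as sequencing is), scaled by a log-normal library size
(mean 14.2 million reads, log2 SD 0.35, matching a realistic small-RNA
depth), and counts are drawn negative-binomially via a gamma-Poisson mixture
with common dispersion 0.15.

**Planted effects** (all log2; defaults in parentheses):

- `lncrna_miliary_logfc` (−1): added to every lncRNA in miliary solid samples.
- `mirna_target_logfc` (−1): added to the verified targets of the designated
  up-miRNAs in miliary solid samples; the up-miRNAs themselves receive the
  mirrored, opposite-sign shift, creating the inverse gene-down/miR-up
  coupling the gene-miR set engine should detect.
- `circ_index_shift` (−1): added to the log2 back-splice rate of miliary
  solid samples. Junction totals are Poisson (~3 splice events per 1000
  library reads), the back-splice share is binomial around a base rate of
  0.05 with log2 SD 0.25 sample jitter.
- `signature_logfc` (+2): separates the signature members by spread type in
  primary (P) samples only, mirroring a P-derived signature and making the
  "only in P" selection rule recoverable.
- `cox_coefficients`: log hazard ratios for the survival table (defaults:
  age/decade 0.38, FIGO 1.02, residual 0.70, grade 0.54, predictor 0.56).

A zero effect vector yields null data with no group structure. Gene sets are
GMT-style collections: one planted set per up-miRNA (three quarters of its
targets plus random padding) plus random null sets.

**Survival.** One record per patient. Event times are exponential with rate
λ₀·exp(Σ βx); censoring is uniform administrative on (0, 120 months); λ₀ is
calibrated by root-finding so the *expected* event fraction matches the
target (default 78/165 ≈ 47%). Covariate marginals: age ~ N(5.6, 1.1)
decades, FIGO (II/III/IV) with probabilities (0.05, 0.75, 0.20), residual
tumor Bernoulli(0.5), grade 3 Bernoulli(0.8), predictor Bernoulli(0.5)
(inside generated cohorts the predictor covariate is the true miliary
indicator instead).

**What the generator does not emulate.** Raw reads, isomiR sequence
structure, realistic miRNA-target network topology (targets are sampled
uniformly), transcript-length effects, batch effects, and full transcriptome
size. Compositional renormalization means large planted shifts slightly
perturb unshifted biotypes (as real CPM data would); at desk scale the
planted target suppression measurably moves the miRNA/long-RNA ratio, a
composition artifact that would be much weaker on a 20,000-gene
transcriptome. Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed noise model, not performance on any
real cohort.

## Numerical choices and degenerate inputs

- Permutation p-values use the add-one estimator; ties within float jitter
  (1e-9 relative) count as at-least-as-extreme, keeping degenerate cases
  (e.g. the set of all features) at p ≈ 1.
- Zero residual variance in the per-feature model yields t = 0 for a zero
  effect and ±∞ otherwise.
- Direction ties (score exactly 0) are labeled "up".
- Fisher combination clips zero p-values at 1e-300 with a warning.
- Cox convergence is delegated to statsmodels' Newton-type optimizer; the
  gradient at the reported optimum is checked to < 1e-4 in tests.
- Degenerate inputs refuse loudly: zero library sizes, all-splice-free
  samples, zero-variance t-tests, all-identical predictor scores, monotone
  partial likelihoods, collinear confounders.

## Test problem sizes

Replicate-based tests run on reduced cohorts (23 patients; 300 coding, 100
lncRNA, 60 miRNA, 20 piRNA, 10 snRNA, 10 snoRNA features; 0.5M reads) —
sizes chosen so planted defaults remain comfortably detectable while suites
stay quick. The gene-miR power simulation uses 200 sets (50 planted) over
2000 genes at n = 10+10 with σ = 0.5 and |log2 FC| = 2; Cox recovery and
transfer calibration use 200–400 replicates of n = 165 with ~78 events.

## Known limitations

- The per-feature OLS engine ignores within-patient correlation when A/S and
  P/M samples are pooled; the confounder absorbs tissue-level means only.
- The competitive permutation null is contaminated when a large fraction of
  features carries true effects, making set p-values conservative in
  heavily perturbed cohorts.
- The lncRNA/coding ratio uses medians, so it is insensitive to shifts
  affecting fewer than half of a biotype's features.
- Transfer validation checks calibration slope, not discrimination; a model
  can pass with modest concordance.
- Breslow tie handling slightly attenuates coefficients relative to Efron
  under heavy ties; survival times here are continuous, so ties are rare.
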