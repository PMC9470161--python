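# Methods

`rhizoqg` re-implements, as a tested pipeline over synthetic data with
recorded ground truth, a quantitative-genetics analysis of rhizosphere
microbial communities in a maize diversity panel grown under two nitrogen
treatments.  The pipeline runs from an ASV count table and a SNP genotype
matrix to community ordination, group-level "rhizobiome traits",
heritability, selection differentials against a canopy-coverage fitness
proxy, MAF-dependent genetic-architecture parameters, mixed-model GWAS with
hotspot windowing, and microbe–phenotype integration.  This note records
the models, the defaults and why, the numerical choices, and what the
synthetic data do and do not establish.

## The synthetic field study

The generators in `rhizoqg.synthetic` emulate a replicated diversity-panel
field experiment:

- **Design** — 230 genotypes × 2 N treatments (`plusN`, `minusN`) × 2
  replicate quadrants × 3 samples per plot = 2,760 rhizosphere samples;
  n = 6 samples per genotype–treatment.  Within a quadrant genotypes sit in
  incomplete blocks of 24, each split into split plots and split-plot
  blocks, giving the nested random terms of the downstream models.
- **Genotypes** — diploid dosages from a first-order haplotype copying
  chain: within LD blocks of `block_len` SNPs each haplotype copies its
  previous allele with probability `ld_rho` (default 0.5 over 25-SNP
  blocks), fresh Bernoulli(p) draws otherwise, p uniform on the requested
  MAF range.  Dosages are re-oriented to the realized cohort minor allele.
- **Rhizobiome traits** — each group g has a latent sample value
  y = μ_g + treatment + u(genotype) + block + sp + spb + e, with
  Ve = 1 and default design variances (0.10, 0.05, 0.05).  The genotype
  effect u is additive over `n_causal` SNPs whose effect variance is
  proportional to [2p(1−p)]^S_true (default S_true = −1), rescaled so that
  Vg/(Vg + Ve/6) equals the per-group h² target exactly on the realized
  genotypes.  Treatment effects are drawn N(0, 0.6²) per group, matching a
  community in which most groups respond to N in one direction or the
  other.
- **Counts** — per sample, group counts are negative binomial
  (overdispersion size 25) around depth · softmax(latent), with depth
  32,000 reads per sample (the per-sample scale of the emulated study);
  group counts are split multinomially across member ASVs with fixed
  Dirichlet proportions.  At these settings the count layer adds log-scale
  noise that is small against Ve = 1, so h² targets survive the count
  round trip to within a few hundredths.
- **Fitness** — relative fitness w = 1 + Σ s_k z_k + ½ Σ c_k z_k² + ε on
  standardized genetic values, ε ~ N(0, 0.3²); canopy coverage
  CC = 50 · w.  Because w is generated on the relative scale with mean 1,
  the generating (s, c) are directly the Lande–Arnold-style differentials
  the estimator targets.  Rare non-positive draws are floored at 1e-6
  (fitness is non-negative) with a logged count.
- **Expression** — log2-scale gene × tissue means; a designated gene set
  is shifted upward by `root_boost` in root tissues only.

What the generator does **not** model: spatial field autocorrelation,
multi-year environments, compositional interactions between groups beyond
the shared softmax denominator, taxonomy errors, or sequencing batch
effects.  Passing recovery tests therefore demonstrate correctness of the
estimators under their own assumptions, not robustness to those field
realities.

## Trait construction

ASVs are kept when their mean relative abundance and prevalence clear
thresholds (defaults 1e-4 and 10%) in **every** level of a reproducibility
grouping (year by default).  Groups are formed at the finest non-Unknown
rank of genus → family; Unknown-genus ASVs become "f_<Family> Unknown
Genus" groups, fully unknown ASVs a flagged "Unclassified" group.  A taxon
whose member ASVs respond to N treatment in opposite directions
(per-ASV Welch t, p < 0.05, opposite signs) can optionally be split into
numbered subgroups.  This taxonomy-plus-response rule approximates a
sequence-similarity clustering whose full criteria are not reproducible
here and is labelled as an approximation in outputs.

The trait value is ln((group count + 1) / sample total); the single
pseudocount is added to the group total, not per ASV, so nonzero counts
follow the plain ln(group/total) formula.  Differential abundance between
treatments uses Welch's t-test at p < 0.05, three classes
(`plusN_enriched`, `minusN_enriched`, `ns`).

## Community analysis

Bray–Curtis on relative abundances is the no-tree default; weighted
(normalized) UniFrac via scikit-bio when a tree is supplied.  PCoA is
classical double-centering; negative eigenvalues are reported, not
corrected.  CAP is distance-based RDA: PCoA coordinates regressed on the
one-hot design, fitted values eigen-decomposed into constrained axes.
PERMANOVA uses Anderson's pseudo-F with p = (#{F_perm ≥ F_obs}+1)/(B+1),
seeded label permutations, optional strata, and full enumeration on tiny
designs (the exhaustive path is the oracle for the Monte-Carlo path in the
tests).  Permutations are unrestricted by default; whether the original
analysis permuted within year/block strata is unknown, so strata are an
option rather than the default.

## Heritability

The statistic is the repeatability-style line-mean form
h² = Vg / (Vg + Ve/n) with n = 6, estimated from within-treatment
sample-level data with genotype as the only random term — the h²
definition above has no slot for other components.  Balanced one-way REML is the
closed-form ANOVA estimator truncated at the Vg ≥ 0 boundary (this
equivalence is tested to 1e-6 against the ANOVA oracle); unbalanced data
fall back to a profiled 1-D REML optimization of the variance ratio.
Significance comes from shuffling genotype labels (default B = 1000 in the
library, 199 in the desk-scale drivers) with the +1/(B+1) estimator, which
makes the attainable size at B = 199 equal to 9/200 = 4.5% rather than 5%.

Two caveats are deliberate consequences of this model choice.
First, plot-level covariance (block / split-plot variance) is absorbed
into Vg, biasing h² upward, and the label-permutation null cannot
distinguish it from genotype signal — with the generator's nonzero design
variances every group can appear significantly heritable.  The
parameter-recovery and size simulations therefore set the nuisance design
variances to zero, so that "true h²" is well defined for the estimator
being tested; `fit_variance_components(..., extra_random=...)` exposes the
multi-term alternative.  Second, the estimator's recovery error at 200
genotypes and n = 6 is dominated by sampling of genotype means (MAE ≈ 0.05
across h² ∈ {0.2, 0.5, 0.8}).

Multi-term REML (the BLUP model y ~ (1|genotype) + (1|block) +
(1|split_plot) + (1|split_plot_block) + error, fitted per treatment) is
computed by direct Nelder–Mead optimization of the REML criterion on log
variances, evaluated through the Woodbury identity on the q×q
random-effect system (one Cholesky plus one triangular solve per
evaluation).  Components below 1e-8 of the response variance are reported
as 0.  BLUPs come from the mixed-model equations; traits sharing a design
reuse the previous optimum as a warm start after scaling the response to
unit variance.  A factor that aliases genotype is rejected with an error
naming the pair.

## Selection differentials

Per trait and treatment, relative fitness w = CC/mean(CC) is smoothed on
the standardized genotype BLUPs with a penalized cubic regression spline:
cubic B-splines on uniform knots (basis dimension 12) with a third-order
difference penalty, so linear **and quadratic** polynomials span the
unpenalized null space and are reproduced exactly at any penalty.  The
linear differential s is the average first derivative of the fitted
function over the observed trait values and the quadratic differential c
the raw average second derivative (no ×2 or ½ convention beyond the
definition).  Two numerical choices matter:

- A second-derivative penalty (the common smoothing-spline default) was
  rejected because it shrinks exactly the quantity c estimates; with it,
  bootstrap intervals for c sit around the shrunken value and miss the
  generating curvature.
- The penalty weight is chosen by REML, not GCV.  On near-polynomial
  fitness surfaces the GCV profile is almost flat and picks near-zero
  penalties whose wiggly fits make the average derivative explode in
  bootstrap resamples (boundary gaps in resampled z); REML reliably picks
  the smooth fit.  Numerically exact fits tie across penalties and the tie
  resolves toward the smoothest model.

Significance is a genotype-level bootstrap (resampling (z, w) rows with
replacement, degenerate resamples redrawn and counted) with two-sided
sign-crossing p-values and percentile intervals.  Under the recovery
conditions (s = 0.2, c = −0.05, noise 0.3, 230 genotypes) both intervals
cover the truth in ≥ 90% of replicates.

## Genetic architecture (BayesS)

LD pruning is greedy and windowed (defaults 100-kb windows advanced by 100
SNPs, r² ≥ 0.1 removed, lower-MAF SNP dropped, ties to the larger
position), after a MAF ≥ 0.01 filter.

The architecture model is a spike-slab whole-genome regression
y = 1μ + Xβ + e in which β_j is non-zero with probability π and then
N(0, σ²_β·[2p_j(1−p_j)]^S).  The Gibbs sampler uses residual-update
single-SNP moves, conjugate Beta and scaled-inverse-χ² updates, and
random-walk Metropolis for S on its conditional given the non-zero
effects, with the step adapted to 20–40% acceptance during burn-in and
then frozen.  Numerical choices:

- log 2p(1−p) is centered before entering the effect-variance term; this
  reparametrization (absorbed by σ²_β) decorrelates S from the slab scale
  and visibly tightens the S posterior.
- Priors: π ~ Beta(1, m/25); σ²_β, σ²_e ~ scaled-inv-χ²(ν = 4, scales set
  from the data variance); S ~ N(0,1) truncated to [−5, 5].  The π prior
  is deliberately sparse: with a weaker prior (Beta(1, m/100)) a
  zero-signal trait equilibrates at the prior mean (the slab collapses and
  inclusion carries no penalty), violating the expectation that a null
  trait keeps non-zero-SNP counts below 2% of the panel.
- Desk-scale default chain: 25,000 iterations, 5,000 burn-in, thin 10;
  longer cluster-scale chains go through the config.  The kernel is
  numba-compiled and bit-reproducible under a fixed seed single-threaded.

Classification: purifying if the 95% equal-tailed credible interval of S
lies below 0, positive if above, else neutral (equivalent to a two-sided
posterior p < 0.05; the level is configurable).  Sign recovery is
asymmetric: under S > 0 the low-MAF causal effects are generated small and
are undetectable, so the observed MAF–effect slope suffers winner's-curse
attenuation and wider posteriors than under S < 0.  The sign-recovery
simulations therefore use a strong-signal architecture — 200 causal SNPs
at h² = 0.98 on a 500 × 2,000 panel — under which both signs classify
correctly in ≥ 80% of replicates and neutral traits keep 0 inside the
interval.

## GWAS and MAPLs

The scan is a linear mixed model per trait and treatment with the centered
(VanRaden) kinship K = WWᵀ/(2Σp_j(1−p_j)) and the top three kinship
principal components as covariates.  P3D/EMMAX is the default: K is
eigendecomposed once, the null variance ratio δ = σ²_e/σ²_g is estimated
by REML (grid on log δ plus bounded refinement), then fixed for per-SNP
weighted-least-squares Wald t-tests with per-SNP residual variance — so
with K = I the scan reduces exactly to ordinary least squares (tested to
1e-8).  An exact mode re-optimizes δ per SNP for cross-checks; the two
agree within 0.2 −log10(p) units for ≥ 99% of SNPs on simulated data.
Genomic-control λ is reported per scan; on structured nulls its mean sits
in [0.9, 1.1] while naive OLS exceeds 1.2.

The Bonferroni threshold is −log10(α/Meff) with Meff from the Li–Ji
eigenvalue summary f(λ) = I(λ ≥ 1) + (λ − ⌊λ⌋), computed chromosome-wise
over blocks (default 200 SNPs) of the SNP correlation matrix; eigenvalues
are rounded to 8 decimals first so numerically-integer spectra (duplicate
SNPs give exactly 2) land on the correct side of the floor.  The summary
is noise-sensitive exactly at integer eigenvalues, so a duplicated pair
inside a large noisy block counts as ~1.5 rather than 1; the redundancy
property is exact on pair-sized blocks.  A user-supplied Meff (e.g. a
reference effective SNP number) passes through unchanged.

MAPLs: every significant SNP–trait–treatment association contributes one
signal to its fixed, non-overlapping 10-kb window ([k·10⁴, (k+1)·10⁴),
anchored at 0 per chromosome); windows with ≥ 1 signal are loci, a
stricter subset requires ≥ 2.  Adjacent significant windows are not
merged, and the same SNP significant for two traits counts twice.  Genes
are attached when their transcribed span (1-based GFF coordinates) is
completely contained within ±10 kb of the window; partial overlaps are
excluded.  Allele stratification at a chosen SNP compares trait values
between major-homozygote genotypes and minor-allele carriers
(heterozygotes join the minor group by default — inbred panels have few —
with a policy flag), by Welch's t; groups under 3 genotypes report means
with a suppressed p.

## Integration

Microbe–phenotype correlations are Pearson on genotype-level BLUPs versus
genotype-level plant-trait values, per treatment (sample-level correlation
would inflate n).  Whether more groups pass p < 0.01 than chance is tested
by shuffling the genotype labels of the plant trait and recounting
(p = (#{count_perm ≥ count_obs}+1)/(B+1)).  The heritability–correlation
relation is a per-treatment Pearson correlation between group h² and the
signed CC correlation.  Expression of MAPL genes versus all other genes is
compared per tissue by Mann–Whitney U (expression distributions are
heavy-tailed), with the effect reported as the difference in mean log
expression.  The summary ledger re-derives every flag from the source
tables (heritable, selection class, MAPL membership, CC correlation) and
reports the intersection set; no count is stored independently of its
source table.

## Problem sizes in the shipped drivers

The analysis drivers and the acceptance script run the full pipeline at
desk scale as the package's own configuration: 230 genotypes × 2,760
samples, 2,000 SNPs on 2 chromosomes, 50 microbial groups, B = 199
permutations for heritability, B = 400 bootstrap for selection, 25k
MCMC iterations, and recovery simulations of 20–50 replicates per claim.
Full-study scales (millions of SNPs, 410k-iteration chains) are reachable
through the same configs on a cluster but are not exercised here.

## Known limitations

- The taxonomy-based clustering only approximates sequence-similarity
  grouping; groups are exactly recoverable in the synthetic data because
  taxonomy there is informative by construction.
- The repeatability h² inflates under plot-level covariance (above); the
  permutation test inherits the same blindness.
- Selection differentials are univariate; correlated traits can produce
  indirect-selection signals on non-causal groups.
- The BayesS S posterior is information-limited for positive S at desk
  scale; neutral calls for weakly positive architectures are expected.
- PERMANOVA assumes exchangeability under the unrestricted null; with
  strong block structure, within-strata permutation (provided as an
  option) is the more defensible null.
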