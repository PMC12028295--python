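# Methods

## Scientific background

Ectomycorrhizal (EcM) fungi colonize tree roots and trade soil nutrients for
plant carbon. Whether an EcM community on a given host is assembled by
*neutral* processes (dispersal and ecological drift from a shared regional
pool) or by *niche* processes (host filtering, environmental selection) is a
central question in forest microbial ecology. This package implements a
complete analysis of that question for amplicon (ASV) data from a crossed
host design — host type (conifer / broadleaf) x developmental stage
(juvenile / adult) with replicated root samples — together with a synthetic
community generator that provides ground truth for validating every stage.

## The abundance–occupancy neutral fit

Under neutral assembly, a taxon's occurrence frequency across samples
(occupancy, f_obs ∈ [0,1]) is a tight monotone function of its mean relative
abundance: abundant taxa are everywhere, rare taxa are patchy, and the
relationship carries no host signal. `NeutralOccupancyGAM` fits this curve
per host group:

* response: per-ASV detections out of the group's n samples
  (binomial, logit link);
* predictor: log10 mean relative abundance within the group;
* smoother: penalized cubic B-splines, basis dimension k = 10
  (including the intercept column), penalty chosen by generalized
  cross-validation GCV(α) = n·D(α)/(n − edf(α))² over a log-spaced grid
  10⁻³…10⁴, with edf the trace of the hat matrix.

Two statistics summarize each group:

* **pseudo-R² = 1 − D_res/D_null** — the share of occupancy deviance
  explained by abundance alone. High values mean the community looks
  neutral; low values mean occupancy is decoupled from abundance, the
  signature of host/environmental filtering.
* **m = Σ f_obs(1−f_obs) / Σ f_pred(1−f_pred)** — the ratio of observed to
  fitted occupancy binomial-variance terms. The formula is computed exactly
  as written; note that it equals 1 when observed and fitted occupancies
  coincide, so its reading as a "migration rate" is a convention of the
  originating framework and is deliberately left to the user. The package
  reports both statistics without interpreting m.

Numerical choices: ASVs absent from a whole group are excluded (the log of
zero abundance is undefined); no other trimming is applied, including
f_obs = 1 taxa. If a group has fewer unique abundance values than basis
functions the basis is reduced with a warning (floor k = 4). A group where
every ASV has identical occupancy is fitted as an intercept-only binomial
GLM with pseudo-R² = 0 — the smoother cannot beat the null there, and
statsmodels' penalized IRLS would flag the exact constant fit as perfect
separation. The 95% band is the pointwise Wald band on the link scale
(fit ± 1.96 SE, back-transformed), evaluated on a 100-point abundance grid.
Fits with fewer than 10 ASVs are refused.

## Preprocessing rules

Starting from an integer ASV x sample count table:

1. **Low-count cell zeroing** (default min_count = 10): any cell with
   0 < count < 10 is set to zero. This is a per-cell *presence* correction —
   the aim is removing spurious presences (index bleed, tag switching), not
   removing taxa, so a well-supported ASV keeps its other cells.
2. **Single-sample ASV removal**: ASVs now detected in < 2 samples are
   dropped (likely artifacts).
3. **EcM guild filter**: only ASVs flagged ectomycorrhizal at genus level in
   the taxonomy table are retained.
4. **Rarefaction**: each sample is subsampled without replacement
   (multivariate hypergeometric draw) to a common depth; samples below the
   depth are dropped with a logged warning. The pipeline default depth is
   the post-filter minimum sample total, mirroring rarefy-to-minimum
   practice; the study-scale depth of 23,167 reads is the simulator's
   per-sample default.

The order (presence correction before occupancy-based removal, guild filter
before rarefaction) applies corrections to presences before any rule that
counts presences. The chain is idempotent and every step is recorded in a
provenance JSON (parameters, seed, dropped samples/ASVs).

## Synthetic communities and what they do (not) show

`generate_study` emulates the crossed design: 2 host types x 3 species x 2
stages x 10 replicates = 120 root samples at 23,167 reads each, over a
metacommunity of 300 EcM ASVs with lognormal(0, 1.5) abundances plus 20%
non-EcM decoy ASVs (so the guild filter is exercised). Two regimes with
known truth:

* **Neutral** (adults by default): sample compositions are Dirichlet draws
  with concentration N_T·m_sim·p (N_T = depth, p = metacommunity), then
  multinomial read sampling. m_sim ∈ (0,1] (default 0.5) controls coupling
  to the pool: larger m_sim, lower between-sample variance.
* **Niche** (juveniles by default): per host species, compositions are
  deterministic, ∝ p_i·a_i^s with affinity a and filter strength s
  (default 2). Default affinities model sparse host specialists:
  Bernoulli(0.5) host-presence times LogNormal(0, 0.5) intensity. The
  exponent convention 0⁰ = 1 makes s = 0 reduce exactly to multinomial
  sampling from the pool.

On these defaults the neutral (adult) groups fit the occupancy curve with
pseudo-R² ≈ 0.98 and the niche (juvenile) groups ≈ 0.3–0.45, and the
adult > juvenile ordering is essentially certain per replicate. Two honest
caveats about realism. First, the niche groups do not reach the very low
pseudo-R² (< 0.1) seen in strongly filtered field data: with deterministic
within-host compositions, the only occupancy–abundance coupling left is the
detection-threshold rise (rare taxa are missed at finite depth), and that
rise — shared with the neutral curve — already explains ~30–40% of
deviance. Field data add per-sample environmental scatter that the
generator deliberately omits (its niche law is host-deterministic by
contract). Second, passing the discrimination property shows the fit ranks
regimes correctly, not that absolute pseudo-R² values are transferable to
real studies. The generator has no spatial dispersal, no phylogenetic
structure, and no sequence-level error.

## Diversity and group comparisons

Alpha diversity per sample: Shannon H = −Σ p ln p (nats), Gini–Simpson
1 − Σ p², Pielou J = H/ln S (undefined and reported missing at S = 1),
observed richness S. Group tests follow a declared decision rule: Shapiro–
Wilk normality per group, Levene and Bartlett variance homogeneity across
groups, all at α = 0.05; one-way ANOVA when all pass, Kruskal–Wallis
otherwise. The full assumption record (all three p-values and the binary
outcome) is attached to every test so the choice can be audited — the rule
itself is a package convention, since variance tests are sometimes loosely
described as normality checks in the field literature.

Beta diversity: Bray–Curtis dissimilarity on Hellinger-transformed (square
root) relative abundances; NMDS (nonmetric, Kruskal stress-1, 20 random
starts, tolerance 1e-7) with normal-theory 95% ellipses per group
(chi-square radius on the coordinate covariance); single-factor PERMANOVA
(Anderson's SS partition: R² = SS_between/SS_total, pseudo-F) and ANOSIM
(Clarke's rank R) with the (1 + exceedances)/(1 + permutations) p estimator
at 999 permutations by default. Factors are tested separately (stage, host
type); a joint model is intentionally not the default since the appropriate
formula depends on the design.

## Indicator taxa

A 1000-tree random forest on per-sample relative abundances ranks ASVs by
association with a binary contrast; the default ranking metric is mean
decrease in impurity. Permutation importance is available
(`n_permutation_repeats > 0`) and takes over the ranking when computed, but
is not the default: rescoring a 1000-tree forest for every ASV x repeat is
two to three orders of magnitude slower than the impurity read-out, and on
the planted-effect benchmarks impurity ranking already recovers ≥ 95% of
truly differential taxa. The top 30 ASVs (configurable) get:

* **lnRR = ln(mean_A/mean_B)** on relative abundances with a nonparametric
  bootstrap 95% CI (resampling samples within groups, 1000 draws). The
  orientation is juvenile/adult for stage and conifer/broadleaf for host
  type, recorded in the output. A zero group mean yields a ±infinity
  sentinel with a one-sided flag rather than a pseudo-count, so exact zeros
  stay visible; a pseudo-count alternative can be layered on by callers.
* per-ASV ANOVA/Kruskal–Wallis p-values (same decision rule as diversity),
  reported raw and Benjamini–Hochberg adjusted.

## Problem sizes used in validation

The test-suite and acceptance-script simulations use the full 120-sample
design for the regime-discrimination property (100 replicates), 1,000
random vector pairs for the migration-statistic oracle, 100 random tables
for the diversity/Bray–Curtis oracles, 200 seeded null datasets at 199
permutations for PERMANOVA calibration, and 50 seeded 300-ASV datasets with
10 planted 4-fold effects for indicator recovery — sizes chosen so the whole
validation runs in a few minutes on one core while keeping Monte-Carlo error
well below the margins being asserted.

## Known limitations

* The GAM variant of the neutral fit is not the classical beta-binomial
  maximum-likelihood neutral model; the Sloan-style m estimate from that
  model is not computed (the occupancy-variance ratio above is reported
  instead, as defined).
* PERMANOVA is single-factor; no dispersion (betadisper-style) diagnostic
  accompanies it, so location and dispersion effects are confounded as in
  any plain PERMANOVA.
* Bray–Curtis is a semimetric; NMDS handles this, but no correction is
  applied for negative-eigenvalue phenomena in the SS partition.
* The BIOM reader/writer covers the dense-count HDF5 (2.1) layout used
  here — counts plus ids — not arbitrary BIOM metadata payloads.
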