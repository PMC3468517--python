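# Methods

This note documents the statistical models implemented in `aflpzone`, the
choices made where the design was open, and what the synthetic-data tests
do and do not demonstrate.

## Dominant markers and allele frequencies

AFLP loci are anonymous dominant markers: the band phenotype is `present`
for both the presence-homozygote and the heterozygote, so only the
band-absence count k out of n individuals is informative.  Under
Hardy-Weinberg equilibrium the band-absence probability is x = q², with q
the absence-allele frequency.  Three estimators are provided:

* **square root** — q̂ = √(k/n).  Consistent but biased downward at small n
  (concavity of the square root).
* **Lynch–Milligan** — q̂ = √x̂ · (1 − Var(x̂)/(8x̂²))⁻¹ with
  Var(x̂) = x̂(1−x̂)/n, clipped to [√x̂, 1].  Undefined at k = 0; such loci
  fall back to the Bayesian estimator.
* **Bayesian (non-uniform prior)** — a Beta(a, b) prior is placed on the
  band-absence probability x and fitted across loci by the method of
  moments; the posterior of x given k is Beta(a+k, b+n−k) and the point
  estimate is the posterior mean of √x, a ratio of Beta functions.  This is
  the operational form of the Zhivotovsky-style estimator used by
  AFLP-SURV; exact numerical agreement with that program is not claimed,
  but consistency and the shrinkage advantage at small n are verified by
  simulation.

F_IS is assumed 0 throughout this module; inbreeding enters only in the
outlier scan, where it is integrated over a Uniform(0,1) prior per locus.

The polymorphism filter removes loci whose minor *phenotype* frequency is
strictly below the threshold (default 10%) within the sample used for LD;
a locus exactly at the threshold is retained.  Missing cells are excluded
from numerators and denominators everywhere.

## Population structure

**Distances.** Squared Euclidean distance on band phenotypes is the primary
metric (rescaled by L/L_shared under pairwise deletion); band-sharing
(Dice) similarity and Jaccard ("asymmetric binary") distance are provided
for robustness comparisons.  The Dice similarity is a deliberate
simplification of marker-based relatedness — adequate for ordination, not
a pedigree-grade estimator.

**Classical MDS** is the double-centred eigendecomposition of the squared
dissimilarity matrix, eigenvalue-ordered, with negative eigenvalues
dropped under a warning.

**Pairwise F_ST** is a Hudson-style ratio of sums over loci on the
estimated allele frequencies: per locus the numerator is
(p̂₁−p̂₂)² − se₁² − se₂² (the delta-method sampling variance of the
square-root estimator corrects the squared difference) and the denominator
is p̂₁(1−p̂₂) + p̂₂(1−p̂₁).  Under the Balding–Nichols model this ratio has
expectation F; simulation at F = 0.38 (1000 loci, 50+50 dominance-masked
diploids) recovers the truth within ±0.05 for all three frequency
estimators.  The permutation test reassigns individuals to the two
populations and re-estimates frequencies with the same estimator;
p = (1 + #{F* ≥ F})/ (n_perm + 1).

**AMOVA** partitions the squared-Euclidean distance matrix over the 4-level
hierarchy races / populations-in-races / sites-in-populations /
within-sites.  Sums of squares come from within-group pairwise distance
sums; variance components from equating mean squares to their expectations
with unbalanced nested-design (Searle) coefficients.  Negative components
are reported as estimated and truncated at zero only for percentages.
Permutation p-values use the exchangeable unit proper to each level: whole
populations among races, whole sites among populations within race,
individuals among sites within population.  Note that with only two or
three populations per race the race-level permutation distribution is very
coarse (tens of distinct partitions), which is why the recovery test uses
three populations per race; the paper-scale design with 2–3 populations
per race cannot produce small race-level p-values no matter how strong the
signal — a property of the test, not a defect of the data.

**Hybrid index.** In place of a full admixture-clustering model, each
individual's admixture proportion Q toward population 1 maximises the
independent-loci likelihood with mixed presence frequency
p_mix = Q·p₁ + (1−Q)·p₂ and band probability 1 − (1−p_mix)².  The optimum
is located on a 0.001 grid and refined by bounded scalar minimisation.
Individuals with a flat likelihood (p₁ = p₂ at all scored loci) are
flagged unidentifiable.  The hybrid designation rule is strict: an
individual is a hybrid when its assignment toward the nominal parental
population is < 0.98, i.e. at least 2% of the genome is assigned to the
opposite cluster.  The model ignores F_IS and linkage; it is a
single-parameter stand-in, adequate for the 98% rule and for Q recovery
(RMSE ≤ 0.05 at 300 diagnostic loci) but not for tracing pedigrees of
backcrosses.

## Bayesian F_ST outlier scan

Two-population scans only.  Per locus i and population j the population
presence frequency follows the multinomial-Dirichlet (Balding–Nichols)
sampling model p_ij ~ Beta(θ_ij p_i, θ_ij (1−p_i)) with
θ_ij = (1−F_ij)/F_ij and logit(F_ij) = α_i + β_j: β_j is shared drift,
α_i a locus-specific selection effect.  A reversible-jump indicator
switches α_i between 0 and a free value; the prior odds of the neutral
model default to 1.  Dominant data enter through
P(absent) = q² + F_IS·q(1−q) with per-locus F_IS sampled under its
Uniform(0,1) prior.  Priors: α ~ N(0, 1) (the standard choice for this
model class; its Occam penalty protects the null while the enormous
likelihood gain of a fixed difference still forces detection),
β ~ N(−1, 1.8).  Proposal scales are pilot-tuned to acceptance rates in
[0.25, 0.45]; the birth proposal for α is a per-locus normal fitted from a
pilot run with all loci forced into the selection model.

Two sampler details matter for short chains.  First, model switches are
joint moves on (α_i, p_ij): the population frequencies are re-proposed
from data-informed Beta distributions matched to the destination model's
F_ST, because indicator-only birth/death moves leave p_ij adapted to the
old model and trap borderline loci in one basin for thousands of sweeps
(verified against 80,000-iteration reference chains).  Second, the
reported inclusion probability is Rao-Blackwellised: at regular intervals
α is integrated out exactly by Gauss–Hermite quadrature recentred on the
pilot-fitted conditional, and the posterior probability is the average of
these conditional inclusion probabilities — far lower variance than
averaging the indicator.  Reported per locus: posterior inclusion probability,
log₁₀ posterior odds (log PO > 1 read as strong evidence), the q-value
(mean of 1−P over all loci at least as strong — the estimated FDR of the
calling threshold), the posterior mean of α given inclusion, and the
posterior mean locus F_ST.

Because the synthetic generator uses the same Balding–Nichols model for
neutral loci, simulated null datasets are a coherent null for the scan:
at 10,000 iterations (5,000 burn-in, the reduced budget used in tests) an
outlier-free 500-locus pair at background F_ST 0.1 yields no FDR-0.05
detections in ≥ 95% of seeded runs, fixed differences are detected at
log PO > 1 with ≥ 7/10 power, and power degrades at background F_ST 0.4 —
the known high-differentiation false-negative regime.

## Linkage disequilibrium for dominant loci

With haplotype frequencies f_AB, f_Ab, f_aB, f_ab (A, B presence alleles),
HWE and random mating give the four phenotype-class probabilities listed
in the module docstring; the EM algorithm distributes each class's 2n
haplotypes over compatible genotypes (E-step) and renormalises (M-step),
initialised at linkage equilibrium from marginal square-root estimates,
with tolerance 1e−8 on the log-likelihood and at most 10⁴ iterations.
A moment identity (f_ab = √(n₋₋/n) etc.) solves the likelihood equations
exactly whenever feasible; by default the EM result is polished to that
exact solution when it is feasible and at least as likely, which returns
clean boundary values (D = 0.25 for a fully associated table) instead of
an asymptotic EM approach to them.  The estimator is validated against a
brute-force grid search over the haplotype simplex (coarse 0.01 grid plus
local 0.001 refinement) to within 10⁻³ on D.

D = f_AB f_ab − f_Ab f_aB is bounded by |D| ≤ 0.25.  For the hybrid-zone
contrast D is polarised by sign((p−q)(r−s)) — the product of parental
presence-frequency differences — so that parental-combination association
is positive regardless of band coding.

**Migration control.** In an admixed pool, migration alone creates LD
proportional to (p−q)(r−s); the contrast therefore compares outlier×outlier
pairs against neutral×neutral pairs restricted to the same tail of the
product distribution (beyond ±0.75, with ±0.8 available as a sensitivity
setting), one Welch one-tailed t-test per tail (alternative: outlier LD
higher), mixed pairs excluded.  Welch is used because the group variances
differ and pair counts are small; the test treats pairs as independent
although pairs sharing a locus are correlated — a limitation shared with
the original design.

## Synthetic data

The generator emulates the study design: two parental populations (50+50)
under Balding–Nichols differentiation at F = 0.38, seven fixed-difference
outlier loci (alternating direction so both product tails are populated),
600 loci at desk scale, 51 hybrid-zone individuals, dominance masking
always on.  Hybrid Q values follow Beta(2, 2) (mean 0.5, SD ≈ 0.224),
giving a mix of near-parental and strongly admixed genotypes.  Each hybrid
haplotype is a two-state ancestry mosaic along a 10-Morgan map: ancestry
re-draws (Bernoulli(Q)) arrive with intensity g per Morgan, g = 100
generations since contact by default — g is a free parameter, as no
estimate of zone age at generation resolution exists; 100 puts unlinked
loci far past ancestry decorrelation while keeping blocks realistic.  The
resulting admixture LD between fixed-difference loci is
Var(Q) + E[Q(1−Q)]·e^(−g·d).  Inside the rearranged block (0–0.25 M)
ancestry switching is disabled entirely: a switch there would require a
crossover in a block heterokaryotype, where recombination is taken as
completely eliminated, and in homokaryotypes a crossover exchanges
identical ancestry.  Missing data are injected at a configurable rate
(default 0).

A separate balanced 4-level Gaussian design with exactly rescaled nested
effects provides a sharp recovery target for the AMOVA decomposition
(squared-Euclidean AMOVA is agnostic to whether coordinates are band
scores or continuous traits), and a hierarchical Balding–Nichols design
(3 races / 5 populations / 2 sites each) emulates the island-wide
structure for ordination exercises.

**What the generator does not model:** explicit meiosis or karyotypes,
underdominant selection against hybrids, continuous migration into the
zone (admixture is a standing pool with mosaic refinement), spatial
structure (a single admixed pool stands in for the zone centre), genotyping
artefacts beyond uniform missingness.  Consequently, passing tests show
that the estimators recover the parameters of this model class — not that
real AFLP data satisfy HWE within the hybrid pool (they do not, exactly:
the Q-mixture induces a Wahlund excess of homozygotes, which biases
pooled-sample EM LD upward, more strongly for repulsion-phase pairs; the
contrast tests inherit this, as does any pooled-sample dominant-marker LD
analysis).

## Numerical choices

* EM: tolerance 1e−8 on log-likelihood, max 10⁴ iterations,
  linkage-equilibrium initialisation, frequencies floored at 1e−15 and
  renormalised; non-convergence returns the last iterate flagged.
* Grid oracle: coarse step 0.01 over (q_A, q_B, f_ab), local refinement
  step 0.001, infeasible corners masked at −∞.
* MCMC: logit-scale random walks folded back into (0,1) by reflection;
  unit-interval proposal scales capped at 2; pilot tuning 20 rounds × 50
  sweeps, multiplicative scale adaptation (×0.7 / ×1.4) toward acceptance
  0.25–0.45.
* Hybrid index: p_mix clipped to [1e−9, 1−1e−9]; flat-likelihood threshold
  1e−9 on the grid log-likelihood range.
* AMOVA permutation comparisons use a 1e−12 slack so ties count as "as
  extreme"; p-values are (count + 1)/(n_perm + 1).
* All simulations consume `numpy.random.default_rng` seeded explicitly;
  identical configuration and seed give byte-identical outputs.

## Problem sizes used in the checks

The test suite and the acceptance script run the pipeline at reduced but
statistically meaningful sizes chosen as this package's own defaults:
600–1517 loci and ~150 individuals for the zone simulations, 500 loci for
the outlier scans at 10,000 iterations (5,000 burn-in), 1000 (suite) or
400 (script) null datasets for permutation calibration at 200 permutations
each, and 200 random tables for the EM-oracle comparison.
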