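# Methods

## The model

`templink` estimates contemporary effective population size (Ne) from two
temporally spaced samples of biallelic loci. For locus *i* with observed
allele frequencies *x*<sub>i0</sub> and *x*<sub>it</sub> (diploid sample
sizes *S*<sub>0</sub> and *S*<sub>t</sub>, *t* non-overlapping generations
apart, sampling plan II — individuals drawn with replacement, or after
reproduction, so sampling does not perturb the breeding population), the
standardized change is

    delta_i = (x_it - x_i0) / sqrt(x_i0 (1 - x_i0)).

Under Wright–Fisher drift plus binomial sampling at both ends,

    var(delta) ≈ F = 1/(2 S0) + 1 - (1 - 1/(2 Ne))^t (1 - 1/(2 St)),

so the temporal F statistic — F̂a the arithmetic mean of delta², or F̂b the
heterozygosity-weighted ratio of sums — estimates F, and the moment
inversion

    Ne ≈ t / (2 (F̂ - 1/(2 S0) - 1/(2 St)))

gives the point estimate (the harmonic-mean Ne over the interval). An exact
inversion (solving for `(1-1/(2Ne))^t`) is also provided; the two agree to
first order in 1/Ne and the approximate form is the default because it is
the field's standard.

### Linked loci and the Q² interval

The point estimate is insensitive to linkage, but the classical interval —
which treats K·F̂/F as chi-square with K degrees of freedom — is badly
anti-conservative when loci are linked, because the drift trajectories of
linked loci are correlated (pseudoreplication). For a pair of loci with
recombination fraction *c* and standardized LD *r*<sub>0</sub> in the first
sample, the two-locus Wright–Fisher model gives

    cov(p_it, p_jt) = D0 (1-c) [1 - (1 - 1/(2Ne))^t (1-c)^t] / (2 Ne c + 1 - c)

for the true frequencies, and with plan-II sampling

    cov(delta_i, delta_j) ≈ r0 { 1/(2S0) + B - (1-1/(2Ne))^t (1-c)^t [B - 1/(2St)] },
    B = (1-c) / (2 Ne c + 1 - c).

Setting c=0, r0=1 recovers var(delta) exactly — the self-consistency check
the implementation property-tests on a grid. The correlation matrix **R**
of the deltas (off-diagonals = cov/var, variance treated as common across
loci) is assembled from pairwise r0 estimates, recombination fractions, and
a plug-in Ne (the moment point estimate; the interval is robust to roughly
ten-fold mis-specification of this plug-in). With eigenvalues λ₁…λ_K of
**R** (or of K·W^½**R**W^½, W = diag of the F̂b weights),

    K F̂ / F  ~  Q² = Σ λ_i Z_i²,   Z_i iid N(0,1),

a chi-square mixture sampled by Monte Carlo (default 50,000 draws for data
analysis, 10,000 in the replicate study). The 95% CI for F is
[K F̂ / q₀.₉₇₅, K F̂ / q₀.₀₂₅] from the empirical quantiles (linear
interpolation), mapped anti-monotonically onto Ne bounds; the upper Ne
bound is +inf whenever the lower F bound falls at or below the sampling
floor 1/(2S0)+1/(2St). When **R** = I the mixture collapses to chi-square
and the adjusted interval reproduces the classical one. The effective
number of independent loci is K' = 2K²/var(Q²) = K²/Σλ².

### LD estimation and the bias correction

r0 needs only the first temporal sample. Phased haplotypes: direct
haplotype counting, identical to the Pearson correlation of the 0/1
columns. Unphased genotypes: EM maximum likelihood under Hardy–Weinberg
over the double-heterozygote phase ambiguity (convergence tolerance 1e-9 on
haplotype frequencies, 200 iterations; non-convergent pairs fall back to a
Burrows-style composite measure — the correlation of dosages — which does
not assume HWE).

Raw r estimates are inflated by sampling noise (E[r̂²] ≈ r² + 1/n for weak
LD, n = number of sampled haplotypes). We correct on the r² scale,

    r0 = sign(r̂) sqrt(max(0, r̂² - 1/n)),   n = 2 S0,

for both phased and unphased data (n is configurable). This is a
noise-floor subtraction, not an exact unbiasing; its adequacy is validated
by the coverage study rather than by theory. Uncorrected MLE r̂ makes the
intervals somewhat conservative.

Because the correction hard-thresholds small correlations to zero, the
*estimated* **R** is generally not exactly positive semidefinite even
though the population matrix is: a few per cent of eigenvalue mass can go
negative. Estimated matrices are therefore repaired before the mixture is
sampled — negative eigenvalues (pure estimation artifacts) are clipped to
zero and the spectrum rescaled to restore Σλ = K, preserving E[Q²] = K.
Model-derived (exact) matrices are held to a strict tolerance instead:
eigenvalues below −1e-8·K raise, since there they indicate a genuine bug.

### Recombination fractions

Physical distance converts to c by Haldane's interference-free mapping
function c = ½(1 − e^(−2d)), d in Morgans from a uniform cM/Mb rate
(default 1.4 cM/Mb, appropriate for *Anopheles gambiae*), or by exact
per-bp geometric compounding c = ½[1 − (1 − 2ρ)^y] when a per-adjacent-bp
rate ρ is specified (the simulator's convention). Pairs on different
chromosomes/arms are unlinked (c = 0.5) by default; a "through-map" rule is
available for genome-cumulative coordinates. Note that even at c = 0.5 the
delta correlation is not zero — the shared time-0 sample contributes
r0/(2S0) — so cross-arm entries vanish because corrected r0 ≈ 0 for
unlinked pairs, not because of c alone.

### Large K

Eigen-decomposition is the dominant cost (dense symmetric solver, O(K³)).
Above a configurable K (default 20,000) the pipeline switches to a
per-chromosome(-arm) block-diagonal spectrum — exact when cross-arm entries
are zero, which the bias correction approximately enforces — and the
spectra of the blocks are pooled. Q² sampling is chunked over eigenvalues
so memory stays bounded.

## The simulator

The validation engine is a forward Wright–Fisher simulator over the K
retained marker columns only: per generation each of the 2Ne offspring
haplotypes is formed by recombining two uniformly chosen parent haplotypes.
Crossovers are realized as a sparse event process with per-adjacent-interval
intensity d_k = −½ ln(1 − 2c_k): the parity of a Poisson(d_k) count is
Bernoulli(c_k) and counts in disjoint intervals are independent, so at
marker resolution this is *exactly* the independent-Bernoulli-per-interval
(interference-free) crossover model, and the recombination fraction between
any two markers y bp apart equals ½[1 − (1 − 2ρ)^y] identically. The sparse
representation makes a generation cost O(2Ne·K) memory traffic plus O(#
events), a few milliseconds at Ne = 1000, K = 500.

Study defaults mirror the simulation protocol the method was validated
under: chromosome length 1e5 bp, per-bp recombination 1e-5 per generation,
mutation 1e-6 per bp per generation, Ne = 1000 diploids, K ≈ 500 loci,
samples of 50 diploids at generations 0 and 10, MAF < 5% excluded at either
time point (sample frequencies), unphased data mimicked by randomly pairing
haplotypes. Plan-II sampling draws 2S haplotypes with replacement without
touching the population.

**Initialization.** The generation-0 population (all 2Ne haplotypes) is
drawn from the coalescent with recombination and binary mutation (msprime),
using the discrete-time Wright–Fisher model for the most recent 100
generations (exact when the sample is the whole population) and the
standard coalescent deeper in time. This puts the population at
mutation–drift–recombination equilibrium, the regime the method assumes. A
forward-only alternative (`initialization="forward"`: independent loci with
a truncated-1/x frequency spectrum, then a burn-in of
max(4/median-pairwise-c, 200) generations) is retained for diagnostics, but
it was found unsuitable as the default: with negligible recurrent mutation
the conditional LD of tightly linked pairs has no stationary level — it
keeps growing with burn-in length (measured r̄² for sub-2kb pairs: 0.033 at
100 generations, 0.040 at 200, 0.059 at 1600, still rising) — so any
burn-in choice fixes an arbitrary, sub-equilibrium LD level, and the
chi-square coverage in the replicate study is sensitive to exactly that
level. The coalescent start removes the arbitrary knob.

Mutation is off during the t generations between samples (the horizon is
short and the method assumes mutation negligible). Loci whose population
MAF at generation 0 passes the configured threshold are candidates; up to
K_target are retained uniformly at random.

**What the generator does not emulate:** selection (including linked
selection), migration, overlapping generations, population size change
within the sampling interval, genotyping error and missingness, and
fine-scale recombination rate variation. Passing coverage here shows the
interval construction handles linkage and sampling noise correctly under
neutrality and a closed population; it does not validate robustness to
those excluded forces.

## Replicate coverage study

`run_replicate_study` is the machine-readable twin of the method's
validation table: per replicate it simulates a population, draws the two
plan-II samples, applies the MAF filter, computes F̂a (or F̂b) and Ne,
estimates r0 from the generation-0 sample (phased path and/or the
unphased EM path), builds **R** with the plug-in Ne, draws the Q² mixture,
and scores both the adjusted and the chi-square 95% intervals against the
true F from the closed form. At desk scale the study runs 200 replicates
with 10,000 Q² draws (about three minutes on one core); the full
1,000-replicate design is supported by the same function. At 200 replicates
the binomial standard error of a coverage estimate near 0.95 is about
0.015, and near 0.72 about 0.032.

## Numerical choices and edge cases

- F̂ at or below the sampling floor maps to Ne = +inf (a documented
  sentinel), never a negative estimate; the same rule gives infinite upper
  CI bounds.
- `x0 ∈ {0, 1}` makes delta undefined; such loci must be (and are)
  removed by the MAF filter before estimation.
- Empirical quantiles use linear interpolation between order statistics.
- Window pruning keeps one uniformly chosen SNP per non-overlapping
  1,000-bp window (configurable) per chromosome; the MAF filter runs before
  pruning.
- Allele-frequency panels are computed over non-missing calls; loci with
  more than 10% missing calls (configurable) are dropped. For unphased LD,
  missing dosages are mean-imputed — LD only, never the frequency panel.
- All randomness (simulator, window pruning, Q² draws) flows from explicit
  seeds / numpy Generators; repeated runs with the same inputs and seed are
  byte-identical.
- The delta-moment formulas are ratios of expectations: they describe the
  change standardized by the *true* initial heterozygosity. Standardizing
  by the observed x0 — what the estimator necessarily does — adds an
  O(1/S) Jensen-type bias (about +1.5% at S = 50), which is part of the
  known few-per-cent bias of temporal F estimators and is inherited by
  F̂, not a defect of the formulas. The simulator oracle therefore checks
  the formulas with true-heterozygosity standardization.

## Known limitations

- The r0 bias correction is a noise-floor subtraction chosen for
  robustness, not an exact unbiased estimator; with very small S0 it can
  leave the adjusted interval mildly conservative (coverage slightly above
  nominal), which is the safe direction.
- The equal-variance assumption in the correlation matrix ignores
  per-locus differences in var(delta); with a 5% MAF floor this is a
  second-order effect.
- Two time points only, sampling plan II only, biallelic loci only;
  selection-aware and likelihood-based temporal methods are out of scope.
- Generations between samples must be supplied by the user; the estimate
  scales linearly with t.
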