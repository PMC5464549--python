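# Methods

This note records the models implemented, the estimator conventions chosen
where the literature (and the classical programs DnaSP, Arlequin, Network)
disagree, the defaults of the synthetic-data generator, and the numerical
choices that affect results.

## Data model and distances

Sequences are haploid, aligned, equal length, over `A C G T N -`. Haplotype
identity is exact string equality after uppercasing: sequences containing N
or gaps collapse together only when the full strings match. No ambiguity
resolution is attempted, matching the granularity of deposited haplotypes.

All sequence distances are raw pairwise nucleotide-difference counts under
**pairwise deletion**: a site contributes to a pair only when both members
carry an unambiguous base. Programs differ here (complete deletion vs
pairwise deletion), so the choice is recorded in the pipeline's provenance
log. The number of polymorphic sites N_p counts sites with at least two
distinct unambiguous bases across the sequences considered.

## Diversity

Haplotype diversity uses Nei's (1987) unbiased estimator
h = n(1 − Σp_i²)/(n − 1) and its sampling variance
V(h) = 2/(n(n−1)) · {2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)²}.

Nucleotide diversity π (per site) is the mean over all unordered sequence
pairs of (differences / compared sites); this equals the unbiased
haplotype-frequency-weighted form with the n/(n−1) correction. Its default
standard deviation is the square root of the **total** (stochastic +
sampling) variance of a non-recombining locus,
V(π) = (n+1)π / (3(n−1)L) + 2(n²+n+3)π² / (9n(n−1)),
the convention mtDNA studies usually report. Because the sampling-only
alternative is sometimes wanted and its exact formula requires quadruple
sums over sites, the package provides it as a sequence bootstrap
(`pi_sd_method="bootstrap"`) instead; the default is documented in the
output. Pooled (area, total) rows are computed on concatenated samples,
never by averaging member estimates. Reporting precision follows the
field's tables: h to 3 decimals, π to 4.

## F_ST and gene flow

Default estimator: Hudson/Slatkin F_ST = 1 − H_w/H_b with H_w the mean
within-group pairwise difference averaged over the two groups and H_b the
mean between-group difference. It is the estimator whose island-model
inverse Nm = (1 − F_ST)/(2 F_ST) (haploid, maternal marker:
F_ST = 1/(1 + 2Nm)) reproduces published Nm values from published F_ST at
printed precision. Weir–Cockerham's haploid θ (haplotypes as alleles) is
available as an option; it weighs haplotype frequencies only and ignores
sequence similarity, so the two can legitimately differ. Negative estimates
are reported as computed and clamped only for the Nm conversion (F_ST ≤ 0 →
Nm = +∞ with a warning).

A caveat for validation: the identity F_ST = 1/(1+2Nm) is the
infinite-island limit. For a finite island model with d demes the exact
parametric value is 1/(1 + 2M·d/(d−1)) (from E[T_within] = d and
E[T_between] = d + (d−1)/m); the test suite simulates at the rate where the
exact value is 0.5 and cross-checks against msprime.

## AMOVA

Excoffier–Smouse–Quattro nested ANOVA on squared distances, with the
squared Euclidean distance for haplotypic data taken as the raw
nucleotide-difference count (the convention of the standard implementation
for sequence data). Sums of squares come from distance sums within blocks
(SS = Σ_{i<j} d²/n per block); variance components are solved from the
expected mean squares with the unequal-sample-size coefficients n, n′, n″.
Identities Φ_ST = (σ²_a+σ²_b)/σ²_tot, Φ_CT = σ²_a/σ²_tot,
Φ_SC = σ²_b/(σ²_b+σ²_c) hold to 1e-9 by construction and are asserted in
tests.

Permutation schemes (10000 permutations by default, p = (hits+1)/(B+1)):
Φ_ST permutes individuals among locations over the whole data set, Φ_SC
permutes individuals among locations within their area, Φ_CT permutes whole
locations among areas. A zero total variance yields flagged NaN Φ values; an
area with a single location triggers a degenerate-design note.

## Mantel test

Z = Σ_{i<j} X_ij Y_ij with p from random row/column permutations of one
matrix (one-sided "greater" by default, as appropriate for
isolation-by-distance); r is the Pearson correlation of the off-diagonal
entries. For n ≤ 7 an exact mode enumerates all n! relabellings. Geographic
distances are user-supplied when available (over-water routes cannot be
reconstructed from coordinates); otherwise a great-circle fallback is used
and labelled as such in provenance.

## Median-joining network

Bandelt–Forster–Röhl construction with ε = 0 by default: iterate the
minimum-spanning network (union of all MSTs; a positive ε admits
near-minimal alternative links) and add, for each mutually linked triplet,
the site-wise majority median when the star through it is strictly shorter
than the triplet's two cheapest links; repeat to closure. Inferred vectors
are then pruned whenever their removal does not increase the minimum
spanning length over the remaining nodes. Three-way site ties take the base
of the lexicographically smallest parent, and all orderings are broken
lexicographically, so the network is independent of input order. The final
graph keeps tied alternative edges — reticulations are intentional, so the
network's total length can exceed the (asserted-optimal) spanning length of
its node set.

Between-group separation is the minimum-cost path between any member of one
group and any member of the other, with edges internal to either group
costing zero and all other edges (including those through medians) counting
their mutational steps.

Exact reproduction of a published network's step counts is not asserted
anywhere: those depend on the original program's internal ε and
post-processing. The recoverable, tested property is the partition into
discrete sub-networks and the optimality of the retained node set on small
instances.

## Mismatch distributions and the sudden-expansion model

Observed mismatch: histogram of all n(n−1)/2 pairwise difference counts,
computed on individual sequences (not collapsed haplotypes), pooled by
area. The equilibrium distribution is F̂_j(θ) = θ^j/(θ+1)^{j+1}; the
transient distribution after a stepwise change θ0 → θ1 at τ mutational
units ago is

F_j(τ) = F̂_j(θ1) + e^{−τ(θ1+1)/θ1} Σ_{i=0}^{j} (τ^{j−i}/(j−i)!)(F̂_i(θ0) − F̂_i(θ1)).

Limits worth noting: τ = 0 returns F̂(θ0) (the expansion has had no
mutational time to act), τ → ∞ returns F̂(θ1), and θ0 = θ1 returns the
equilibrium for any τ. The curve is truncated at d_max and renormalized;
the truncation deficit is logged. The formula was validated against the
replicate-averaged mismatch of an independent coalescent simulation (L1
distance < 0.02 at 400 replicates).

Fitting minimizes the SSD between observed and model frequencies by
L-BFGS-B with bounds (τ ∈ [0, 2d_max], θ0 bounded by a multiple of the
observed mean, θ1 ∈ [1e-3, 1e5]) and multi-start (20 random starts by
default, fewer inside bootstrap refits). The SSD p-value is the
Schneider–Excoffier parametric bootstrap: simulate B coalescent samples of
the same n under the fitted expansion, refit each, and report
p = (#[SSD_sim ≥ SSD_obs]+1)/(B+1). B defaults to 1000 (configurable; the
classical programs use 10000). The raggedness p-value shares the same
bootstrap (r recomputed on each simulated sample); testing r against
separate neutral coalescent nulls instead is a documented alternative the
package does not implement.

Raggedness follows Harpending's convention r = Σ_{i=1}^{d+1} (x_i −
x_{i−1})² with the boundary class x_{d+1} = 0 and d the largest observed
class — editions differ here, so the convention is unit-tested (point mass
at 0 gives r = 1; uniform over 10 classes gives 0.01).

A caution on single samples: all pairs share one genealogy, so an observed
mismatch deviates wildly from its expectation (large evolutionary
variance). Only replicate averages converge to the model curve; the
bootstrap p-values, not per-sample goodness-of-fit, carry the inference.

## Fu's F_S

θ̂ is the mean pairwise difference per sequence (Fu's original choice, not
Watterson's θ). S′ = Pr(K ≥ k_obs | θ̂, n) under the Ewens sampling
distribution; K is computed exactly as a sum of independent Bernoulli
variables with success probabilities θ/(θ+i), i = 0..n−1 (a
Poisson-binomial convolution — numerically stable for n in the hundreds and
identical to the Stirling-number form, which the tests verify via sympy).
F_S = ln(S′/(1 − S′)); both tails are taken from the same exact pmf so no
catastrophic cancellation occurs. k = 1 (or θ̂ = 0) is flagged rather than
returned as ±∞.

The null distribution conditions on θ̂ (not on S): neutral constant-size
coalescent simulations with infinite-sites mutation at θ̂, each yielding
(k_sim, π_sim) and hence F_S,sim; p = (#[F_S,sim ≤ F_S,obs]+1)/(B+1),
one-sided because expansions push F_S negative. Conditioning on S instead
is a known alternative; it is not implemented.

## Structured-coalescent generator

Haploid n-island coalescent with demes grouped into areas. Time is in units
of N generations (per-deme size); θ = 2Nμ per locus, so a branch of length
ℓ carries Poisson(θℓ/2) mutations. Per-lineage migration rates: mig_within
to a uniformly chosen other deme of the same area, mig_between to a
uniformly chosen deme of another area. A sudden expansion (t, g) multiplies
every coalescence rate by g for times older than t (forwards: the
population grew g-fold at t). With mig_between = 0 and several areas the
TMRCA is infinite unless merge_time is set, at which point all demes
collapse into one small ancestral deme; the generator enforces this.

Mutation model: finite sites with an invariant-site mask (proportion p_inv
drawn once per data set) and HKY-flavoured substitution sampling — each
mutation event hits a uniformly chosen variable site and draws the new base
with probability ∝ π_b·(κ for transitions), the root drawn from the
stationary frequencies. This is a jump-chain approximation of HKY (event
placement is not site-heterogeneous); it suffices for emulating base
composition and transition bias, and the infinite-sites mode (every
mutation a fresh site) is used for all analytic cross-checks (Watterson's
E[S], E[T2] = 1, msprime comparisons).

Shipped defaults (the study conditions the generator emulates): 13 demes of
18–29 samples (312 total) in 3 areas (4/7/2 demes), θ = 10, mig_within = 5,
mig_between = 0, expansion (0.3, 50), merge_time = 2, L = 537 bp, base
frequencies (0.227, 0.166, 0.187, 0.420), κ = 5, p_inv = 0.55. Rationale:
θ·t_exp ≈ 3 pairwise differences within demes gives the observed
high-h/low-π regime (h ≈ 0.75–0.97, π ≈ 0.005–0.013 per site); merge_time = 2
gives ≈ 20+ between-area differences, hence ≈ 75% among-area variance and
zero haplotype sharing; mig_within = 5 leaves mild within-area structure
(Φ_SC ≈ 0.07). κ and p_inv are typical invertebrate-COI values; the base
frequencies are the empirical COI composition the survey design assumes.
What the generator does **not** emulate: recombination (correctly absent
for mtDNA), selection, sequencing error, site-rate heterogeneity beyond the
invariant mask, and geography-dependent migration. Passing tests therefore
show the statistics are computed correctly and the inference is calibrated
under the island-model conditions — not that any particular real survey
meets those conditions.

## Numerical and reproducibility choices

- All permutation/bootstrap p-values use the (hits+1)/(B+1) correction, so
  p ∈ (0, 1].
- Every stochastic routine takes a seed; the pipeline funnels one seed into
  all stages and records it (with estimator choices and the
  pairwise-deletion convention) in `provenance.json`. Identical seeds give
  byte-identical outputs.
- Degenerate inputs: monomorphic samples flag h = 0 exactly, AMOVA Φ as NaN
  with a note, F_S as flagged; groups with fewer than two sequences are
  skipped from diversity tables with a warning.
- Problem sizes used in the shipped validation runs (chosen as desk-scale
  designs): calibration at 200–500 replicates with 99 permutations or 49
  bootstrap draws; τ-recovery at n = 50 with 100 simulations × 99
  bootstrap refits; the default survey at its full 312 samples with 199–999
  permutations.

## Known limitations

- The mismatch optimizer can hit the τ upper bound for flat observed
  distributions; the fit is returned flagged rather than silently accepted.
- Weir–Cockerham θ on haplotype frequencies is provided for comparison but
  has no Nm identity matching the haploid island model.
- The Mantel great-circle fallback underestimates over-water distances for
  coastal species; supply measured nautical distances where they matter.
- The median-joining pruning criterion (MST-length non-increase) is a
  deterministic stand-in for the original program's obsolete-vector sweep;
  on small instances it provably reaches the Steiner optimum (tested), but
  equality with any particular program's output on large data is not
  guaranteed.
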