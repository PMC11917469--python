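# Methods

This note documents the models behind `crossuse`, the defaults and why they
were chosen, what the synthetic data generator does and does not emulate,
and the numerical decisions that make runs deterministic.

## Synthetic populations

The generator emulates the statistical structure of an outbred,
pedigree-connected breeding panel, at configurable scale.

**Genetic map.** `n_chromosomes` linkage groups with lengths drawn uniformly
within ±20% of `mean_length_cM`; markers allocated proportionally to length
and placed uniformly (no marker-density model is imposed). Positions are
real-valued cM; chromosome length is the distance between the outermost
markers. The motivating panel has 28 chromosome pairs averaging 223 cM and
tens of thousands of SNPs; the desk-scale default is 5 chromosomes × ~100 cM
with 2,000 markers.

**Founders and LD.** `n_ancestral_haplotypes` (default 32) base haplotypes
are drawn marker-independently with allele frequencies from Beta(0.5, 0.5)
truncated to `[maf_floor, 1 − maf_floor]` (U-shaped, as SNP panels typically
are after QC; the realized frequency across base haplotypes is forced above
the floor by redrawing violating markers). A panel of `n_parents` is then
produced by `n_mixing_generations` (default 4) rounds of random mating
through the meiosis simulator. LD therefore arises the way it does in real
pedigreed panels — long shared ancestral segments — and decays with map
distance. A coalescent simulator would give more realistic deep ancestry,
but any distance-decaying LD suffices for what downstream stages consume,
and reusing the meiosis module keeps one recombination model everywhere.
Defaults (32 haplotypes, 4 generations) were chosen so that adjacent-marker
r² clearly exceeds long-range r² at the default marker density, comparable
to a closed breeding population.

**Trios.** Each trio is a random distinct parent pair plus one simulated
progeny; progeny are never parents of anything. At full scale, 414
non-progeny genotypes plus 593 trios reproduce a 1,007-member panel
topology.

**Genotyping error.** Each genotype call is independently replaced, with
probability `genotyping_error_rate`, by a uniformly random *different*
genotype (so every hit changes dosage; heterozygous replacements get random
phase). This is deliberately the simplest error model that produces the
short-distance floor seen in trio-consistency curves.

**What is not emulated.** Real marker ascertainment, population structure
beyond one mixing history, missing genotypes, octoploid genetics
(the motivating data are diploidized SNP calls), sex-specific maps, and
selection during the mixing generations. Passing tests therefore show that
the *methods* behave as claimed under realistic LD and noise — not that any
specific real panel would yield the same accuracy values, which depend on
its actual LD and pedigree.

## Meiosis: count-location model

Crossovers per chromosome per meiosis ~ Poisson(L/100) for map length L in
cM; positions i.i.d. uniform; no interference, no obligate chiasma; the
starting haplotype is chosen uniformly per chromosome (chromosomes assort
independently). A crossover at position x switches the source haplotype for
all markers at position ≥ x (half-open intervals; coincident crossovers
cancel, a measure-zero event accepted as-is). Under this model the
recombination fraction between loci d cM apart is Haldane's
r(d) = (1 − e^(−2d/100))/2, which the test suite verifies by Monte Carlo.

Full-sib families draw n gametes from each parent and pair them index-wise
after shuffling one side ("random pairing" made concrete); offspring are
phased by construction.

**Switch errors.** Phasing errors are injected with the same count-location
machinery: per chromosome, switch count ~ Poisson(p × L_cM) with uniform
positions, where p is the probability of a switch between two markers 1 cM
apart; from each switch point onward the two haplotypes are exchanged.
Dosages are invariant — a switch error is invisible to unphased data. The
Poisson mean uses length in *cM*, so that the expected number of switches
between markers d cM apart is p·d, consistent with defining p per cM; with
length in Morgans the injected error would be 100× too small to matter at
any plausible p.

## Phasing and genotyping QC from trios

**Genotyping error.** At markers where both parents are homozygous the
progeny genotype is determined; the mismatch fraction over such markers
estimates the per-call error rate (opposite homozygotes are the informative
case: AA × aa cannot produce AA). Undefined (flagged NaN) when no marker
qualifies.

**Two-locus consistency.** For a within-chromosome marker pair at which at
least one parent is doubly heterozygous, a progeny dosage pair is
*consistent* if some combination of one non-recombinant two-locus gamete
from each parent reproduces it (exhaustive ≤ 2×2 check). Recombinant
gametes are deliberately excluded from the compatibility set — their
frequency is exactly the distance signal the curve measures. The check is
symmetric in parents and markers and invariant to a whole-individual phase
flip, which is unobservable.

**Curves.** Eligible pairs (both-het in some parent, both dosages observed)
are binned by cM distance (default 1-cM bins to 50 cM; pair enumeration is
subsampled to 10,000 pairs per trio, seeded, which is unbiased). Empty bins
report NaN, never zero. Expected curves under known phasing error corrupt
each parent with switch errors at rate p, simulate offspring from the
*true* haplotypes, and score them against the *corrupted* ones — exactly
the situation of real data phased with error rate p; a p = 0 baseline
isolates recombination. Because marker pairs within a family share
offspring, Monte-Carlo error for curve comparisons is computed on progeny
counts, not pair counts.

This module estimates phasing accuracy only from unphased progeny plus
phased parents; it does not wrap any external phasing tool — it consumes
already-phased VCFs or the generator's own truth haplotypes.

## Traits and phenotypes

QTL are drawn uniformly without replacement from the mapped markers with
effects α ~ N(0,1); BV_k = Σ_j Z_kj α_j (purely additive — no dominance or
epistasis, a stated limitation). Phenotypes add N(0, σ_ε²) noise with
σ_ε² = Var(BV)(1 − h²)/h², Var over the phenotyped panel with population
(n) denominator. The default scenario grid is h² ∈ {0.2, 0.5, 0.8} ×
n_QTL ∈ {4, 16, 64, 256, 1024} (15 scenarios); the experiment driver's
desk default shrinks this to 2 × 3 with 3 replicates. "Large-effect" QTL
are reported by marginal variance share α_j² Var(Z_j)/Var(BV) (LD
covariance terms ignored; the shares are the standard per-locus reporting
convention and need not sum to one). The t-ratio bound 1/(4L) is reported
against the nominal QTL count; estimating an "effective" locus count from
data is out of scope.

## Genomic prediction

Both models regress phenotypes on column-centered dosages of the non-QTL
markers ("the markers you would actually have", with causal loci excluded
so signal flows through LD only). Centering constants are stored in the
model so new genotypes are centered identically; no scaling beyond
centering, keeping effects on the dosage scale of the BV definition.

**RR-BLUP.** y = 1μ + Xβ + e with β ~ N(0, σ_β² I). REML on the n×n kernel
K = XXᵀ (n ≪ markers): since X is centered, K1 = 0 and centering y is the
restricted projection; the profile likelihood in δ = σ_e²/σ_β² is maximized
on the centered spectrum (bounded search on log δ ∈ [−12, 12], xatol 1e-8),
then β̂ = σ_β² Xᵀ V⁻¹(y − ȳ). Deterministic in (y, X). A fixed variance
ratio can be supplied, which reduces to ridge regression (used by the
closed-form test). Degenerate inputs (constant y, zero X) return the null
model rather than failing.

**BayesC.** Spike-and-slab Gibbs: per-marker inclusion δ_j ~ Bernoulli(π),
shared slab variance σ_β² and residual σ_e² with scaled-inverse-χ² priors
(df 4; scales split Var(y) evenly between genetic and residual signal), and
π ~ Beta(1,1) (estimated by default; can be fixed — π = 1 with fixed
variances is exactly ridge, a model-equivalence check in the tests).
Single-site updates with residual downdating; reported effects are
posterior means of δ_j β_j, with posterior inclusion probabilities kept as
diagnostics. Defaults 10,000 iterations / 2,000 burn-in / thin 10; tests
and the desk-scale driver use shorter chains (≈1,500–2,500 iterations),
which the equivalence and recovery checks show are sufficient at those
problem sizes. Non-finite variance draws abort with state information.

## Cross prediction

True values use the causal effects on QTL dosages; predicted values use
estimated effects on non-QTL markers. The two scales differ, so only
Pearson correlations are ever compared between them, and intercepts —
constant across families — are omitted from gamete scores.

Family summaries come from either 200 simulated offspring per cross
(matching the study conditions) or the gamete-sum method: score n gametes
per parent (default 200), then μ̂_jl = μ̂_j + μ̂_l and
σ̂²_jl = σ̂²_j + σ̂²_l. For additive traits an offspring value is the sum of
two independent gamete values, so means and variances add; the gamete-sum
σ̂ is by construction invariant to how gametes are paired into offspring.
Sample statistics use the n−1 denominator throughout (at n = 200 the
distinction is negligible but must be fixed for determinism).

## Selection and gain

Truncation intensity i(p) = φ(Φ⁻¹(1 − p))/p; the two study intensities are
bound to p ∈ {0.20, 0.01}. Arbitrary i is accepted by inverting i(p)
numerically (Brent on (0,1)), since gain evaluation needs p. Greedy
selection sorts candidate crosses by score (ties broken lexicographically
by parent ids, keeping seeded runs deterministic) and accepts a cross iff
neither parent is already used; exhaustion returns a shorter plan with a
warning. Elite (two-stage) designs first truncate parents on predicted BV
(ties by id), then run the same greedy pick among elite crosses only.

Expected gain of a plan simulates 200 true offspring per selected cross
(cheap — only ~10 crosses per plan) and averages the top-p offspring mean
per cross, rather than using the normal approximation μ + iσ; the normal
form serves as the test oracle at large family size. Gains are standardized
by the mean and additive SD of true BVs over the full parental panel (the
natural reference; no other centering constant is implied by the design).

## Problem sizes and determinism

All randomness flows through injected `numpy` Generators; per-stage seeds
derive from a master seed via `SeedSequence`, so equal seeds give
byte-identical outputs (the experiment driver's resume path re-reads cached
CSVs with round-trip float parsing to preserve this). The test suite and
the acceptance script run at desk scale — populations of 120–300 parents,
600–2,000 markers, 30–200 offspring or gametes per family, 5–10 trait
replicates per trend — chosen so the full pipeline exercises every stage in
minutes while keeping Monte-Carlo error well inside the asserted margins.
`paper_profile()` carries the full-scale configuration (1,007 parents,
28 chromosomes, ~35k markers, 20 replicates, BayesC); it is hours-scale and
not exercised by the tests.

## Known limitations

Additive architectures only; a single mixing-history population model (no
migration, selection, or structure); no interference in meiosis; no
missing-data handling beyond exclusion; the heterozygosity proxy for family
SD is reported but, having different units than σ, is not converted into a
usefulness prediction; and no closed-form family-variance prediction from
recombination fractions — variances come from simulated gametes or
offspring only.
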