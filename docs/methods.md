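# Methods

## Data model

The unit of analysis is a taxon-by-sample binary occupancy matrix
(`PresenceAbsenceMatrix`). Raw read-count tables are binarized by a strict
threshold: a taxon is present in a sample iff its count **exceeds**
`min_reads` (default 100, the conventional cutoff for shotgun-classifier
output; a count of exactly 100 maps to absent). The threshold is monotone:
raising it never converts an absence into a presence. All-zero samples are
retained — they are legitimate co-absent sites — and taxa that end up
present nowhere (or everywhere) are kept in the matrix but flagged
*degenerate* in pair results rather than silently dropped, so pair counts
stay auditable.

Each unordered pair (i, j), enumerated as i < j in input row order, reduces
to the 2×2 table (a, b, c, d) with a+b+c+d = N samples. Per-taxon prevalence
is the row mean; it always equals (a+b)/N for any pair in which the taxon is
species 1.

## Metrics

* phi coefficient: r = (ad − bc)/√((a+b)(c+d)(a+c)(b+d)), undefined when any
  marginal is zero. The radicand is evaluated as two pairwise square roots so
  intermediates stay in float range; agreement with 50-digit decimal
  evaluation is property-tested to a relative 1e−12 on cells up to 10^4.
* Jaccard's index: J = a/(a+b+c), undefined when a+b+c = 0. J never involves
  d, so it is invariant along any co-absence sweep; r is not, and
  `coabsence_sweep` exposes its monotone growth (and possible sign reversal)
  in d at fixed (a, b, c).
* Degenerate denominators return an explicit `defined=False` value rather
  than a sentinel number or an exception, so the all-pairs engine can count
  and report degenerate pairs.
* Under independent placement at prevalences (p1, p2) the expected-cell
  Jaccard value is p1·p2/(p1+p2−p1·p2); at p1 = p2 = 0.5 this is exactly 1/3.

## Null models for the co-occurrence count

* **Standard binomial null**: a ~ Binomial(n, p) with n = a+b+c and p = 1/3.
  The success probability is implemented as the exact rational 1/3 — the
  value forced by the equal-thirds argument underlying the model — with a
  `literal` mode using 0.33 for replicating the printed formula. This null
  encodes a universal 50%-prevalence assumption and is included as the
  object of critique.
* **Prevalence-specific hypergeometric null**: with m sites holding species
  1, n = N−m not, and k holding species 2, P(X=x) = C(m,x)C(n,k−x)/C(N,k) on
  support max(0, k−n)..min(m, k); mean km/N. Verified exactly (as rationals)
  against exhaustive enumeration of all C(N,k) placements for every
  parameter combination with N ≤ 8, and role-symmetric in the two species.
* **Monte-Carlo null**: per trial, both occupied-site sets are drawn
  uniformly at random with fixed sizes (via ranks of iid uniforms) and the
  overlap recorded; 100,000 trials by default, single integer seed, no
  global state. Its total variation distance to the hypergeometric pmf at
  N=286, occ=(30,150) is below 0.01 at that trial count.

Tail probabilities are exact sums over the pmf with the observed point
included in each one-sided tail (standard exact-test convention; mid-P is
not offered). Observed counts outside the support clamp to 0/1 tails so
vectorized loops never branch. Direction is classified by testing each tail
separately at the per-test alpha — positive if P(X ≥ a) ≤ α, negative if
P(X ≤ a) ≤ α, the smaller tail winning in the tiny-support case where both
pass — with no doubling, because direction is read off which side of the
null the observation falls.

Because the two one-sided tests are separate, the combined two-tailed
rejection probability under independence is bounded by 2α, not α; in
practice the discreteness of the exact test keeps the realized rate below α
for long-tail prevalence mixtures (measured ≈0.038 at α=0.05 on the default
synthetic community), though nearly-balanced common-common pairs can exceed
α. This is a property of the separate-tail convention, stated here rather
than hidden.

## Significance of r

The default test is the asymptotic chi-square: p = P(χ²₁ ≥ N·r²),
two-sided; it matches a textbook chi-square on the same table and is the
route most correlation screens use in practice. An `exact` alternative runs
the conditional hypergeometric test on a and doubles the smaller tail
(capped at 1). The choice is configurable because no single convention is
canonical; output records which was used. The chi-square route is knowingly
anti-conservative for pairs of rare taxa (tiny expected cells with huge d) —
that misbehavior is part of what the diagnostics quantify.

## The all-pairs screen

`PairwiseCooccurrence.fit()` evaluates every unordered pair vectorized
(occupancy Gram matrix for a; scipy tail functions on arrays) and applies
Bonferroni: per-test α = family α / n_pairs, so α·n_pairs equals the
familywise level exactly (0.05/844350 at the survey scale of 1300 taxa).
Results carry, per pair: cells, prevalences, r, J, both tails under the
hypergeometric and standard nulls, the r p-value, significance flags and
directions, and the degenerate flag. Since whether the r threshold should
be read two-sided or per-tail is a genuine convention gap, both flags
(`sig_r`, `sig_r_tail`) are emitted.

Diagnostics:

* **Concordance**: the J-significant and r-significant sets compared with
  three distinct denominators — r-only/|sig r|, J-only/|sig J|, and
  both/|union| — plus a direction-match count over both-significant pairs
  (reported, never assumed).
* **Prevalence grid**: pairs binned at 5% prevalence intervals, half-open
  [lo, hi) with the last bin closed at 1.0, placed by (min, max) prevalence
  so the populated region is the upper triangle; layers count total, sig-J,
  sig-r and their difference, and conserve the pair count.
* **Rare-pair fractions**: share of pairs with at least one (and with both)
  members below the rare cutoff (strict <, default 10%).

## Synthetic data

Pairs are parameterized by marginals (p1, p2) and the joint co-occurrence
probability p11 (joint-probability parameterization, matching how
independence is defined for the null), validated against the Fréchet bounds
max(0, p1+p2−1) ≤ p11 ≤ min(p1, p2). Fixed-margin pairs draw exact-size
site subsets uniformly and independently, so their overlap is
hypergeometric by construction.

Communities draw per-taxon prevalences from Beta(1.0, 6.45) over 286
samples × 1300 taxa by default and fill sites as independent Bernoulli
trials; injected associated pairs overwrite designated slots and are
returned in a truth table for recovery tests. The Beta family and its
parameters are a modeling choice calibrated once so the generated matrices
reproduce two shape statistics of the deeply classified skin-microbiome
surveys they emulate: ≈74% of pairs having at least one member under 10%
prevalence, and a median per-pair co-absent fraction near 77%. What the
generator does **not** emulate: read-count noise, classifier misassignment,
compositionality, sample covariates, or any dependence structure beyond the
explicitly injected pairs — so tests passing on synthetic data certify the
statistical machinery, not the biology of any particular dataset.

## Problem sizes and numerical choices

Test-suite simulation sizes are chosen to make sampling error negligible
relative to the asserted margins while keeping the default run fast: 100,000
Monte-Carlo trials for the null-agreement check (TV tolerance 0.01), 5,000
replicates per scenario for the spurious-call demonstration (binomial SE
≈0.003 at α=0.05), a 200-taxon independent community (19,900 null pairs) for
type-I calibration, and 100 seeded 60-taxon communities for the power check
(the injected nested pair's tail p is ~40 orders of magnitude below the
corrected α, so detection failures would indicate a defect, not bad luck).
Analytic pmfs are asserted to normalize within 1e−12; Monte-Carlo pmfs are
exact counts/trials by construction. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`.

## Known limitations

* Bivariate only: no partial correlation or conditional-independence
  adjustment; edges reflect pairwise association (or shared environmental
  response), not direct interaction.
* The exact test is conservative for rare taxa (small supports), which is
  the honest price of exactness at scale; the Bonferroni correction
  compounds this.
* Presence/absence discards abundance information by design; the threshold
  interacts with sequencing depth, and no depth normalization is attempted.
* The separate-tail direction convention bounds the two-sided type-I rate
  by 2α rather than α (see above).
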