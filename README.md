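# cooc

Presence/absence co-occurrence analysis for microbiome (and other
taxon-by-sample) data.

## The problem

Correlation screens on microbial presence/absence (P/A) tables usually reach
for one of two statistics on each pair's 2×2 contingency table — cells
*a* (co-present sites), *b*, *c* (sites holding exactly one of the two taxa)
and *d* (co-absent sites):

* the **phi coefficient** (Pearson's correlation on binary data)

  r = (ad − bc) / √((a+b)(c+d)(a+c)(b+d))

* **Jaccard's index**

  J = a / (a + b + c)

Both are problematic as commonly used. r is driven by co-absences: holding
a, b, c fixed and growing d inflates r and can flip its sign — and in deeply
classified surveys most taxa are rare, so most pairs are dominated by
co-absent sites. J ignores d, but its traditional significance reference —
a Binomial(n, 1/3) null for a out of the n = a+b+c occupied sites — assumes
every taxon sits at 50% prevalence. Off that assumption it manufactures
spurious positives for common taxa and spurious negatives for rare ones.

The fix this package implements is to test the observed co-occurrence count
against the **prevalence-specific hypergeometric null**: with species 1
occupying m of N sites and species 2 occupying k, random site filling gives

P(X = x) = C(m, x) · C(N−m, k−x) / C(N, k)

so each pair gets its own exact null, conditioned on both observed
prevalences. Significance and direction come from the exact tails
P(X ≥ a) and P(X ≤ a), Bonferroni-corrected across all n(n−1)/2 pairs.

The package computes all three routes (exact hypergeometric test for J, the
standard binomial null, and r with a chi-square or exact test) so their
disagreement can be quantified: concordance/Venn summaries, 5%-prevalence-bin
significance grids, and rare-pair composition fractions.

## Worked example

```python
from cooc import (CommunitySpec, InjectedPair, generate_community,
                  PairwiseCooccurrence)

# synthetic long-tail community of 60 taxa over 286 samples, with one
# genuinely associated (nested) pair injected at taxon slots 0 and 1
inj = InjectedPair(i=0, j=1, p1=0.3, p2=0.4, p11=0.3)
spec = CommunitySpec(N_sites=286, n_taxa=60, injections=(inj,), seed=7)
pa, truth = generate_community(spec)

res = PairwiseCooccurrence(pa).fit()
print(res.summary())
print(res.significant_edges("J").to_string(index=False))
```

prints

```
Pairwise co-occurrence screen
=============================
taxa:                60
samples (sites):     286
unordered pairs:     1770
familywise alpha:    0.05 (bonferroni)
per-test alpha:      2.825e-05
r test:              chisq

significant by J (hypergeometric null): 1
significant by r:                       2
significant by both:                    1
frac of sig-r pairs not sig-J:          0.5000
frac of sig-J pairs not sig-r:          0.0000
frac of union significant in both:      0.5000
direction matches among both-sig:       1/1

pairs with >=1 rare member (<10%): 0.683
pairs with both members rare:           0.184
degenerate pairs:                       174

    taxon_i     taxon_j    dir_J        J  p_J_ge_hyper  p_J_le_hyper
taxon_00000 taxon_00001 positive 0.711864  5.835445e-45           1.0
```

The injected pair is the single J-significant edge: its J of 0.71 sits 45
orders of magnitude into the right tail of its pair-specific null. The exact
test calls exactly that one pair; the asymptotic r test also picks up one
spurious rare×rare pair (the "significant by r: 2" line) — the co-absence
inflation the diagnostics exist to expose. Degenerate pairs are those
touching a taxon observed nowhere (or everywhere), counted but never tested
significant.

The same workflow from the shell:

```
cooc synth community.tsv --n-taxa 60 --n-sites 286 --seed 7
cooc threshold counts.tsv pa.tsv --min-reads 100   # for real count tables
cooc analyze pa.tsv out/ --family-alpha 0.05
cooc null --m 30 --n 256 --k 150 --x 20            # inspect a pair's null
```

`cooc analyze` writes the per-pair table (`pairs.tsv`), the significant-edge
list, the prevalence-bin grid layers, a text summary and a reproducibility
manifest.

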