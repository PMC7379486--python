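# Methods

`fibromod` implements a module-based transcriptional screening procedure:
seed a gene module from a few disease markers by coexpression, verify that
the module is switched **on** in disease contrasts, and call a compound a
candidate when the same module is switched **off** (signature reversal) in
its treatment contrast. This note records the models, the defaults and why,
the numerical choices, and what the synthetic evaluations do and do not
demonstrate.

## Marker-seeded module construction

Given a compendium X (genes × samples) and marker set M (default POSTN,
DDR2, PDGFRA — markers of activated cardiac fibroblasts), each non-marker
gene g is scored by its mean Fisher-z correlation to the markers:

    zbar(g) = (1/|M|) Σ_{m∈M} atanh( r(g, m) ),

with Pearson r clipped to ±0.999999 before atanh so a gene duplicating a
marker still gets a finite score (atanh(0.999999) ≈ 7.254). The Fisher
transform makes correlations of different magnitudes averageable on a
common scale.

Significance is a per-gene permutation test: g's sample vector is permuted
`n_null` times (default 999, each gene on its own seeded sub-stream), zbar
recomputed, and the one-sided p-value taken with the add-one convention

    p = (1 + #{null ≥ observed}) / (1 + n_null),

so p ∈ [1/(n_null+1), 1] and is never exactly zero. Only positive
coexpression counts — the module is defined by genes that move *with* the
markers. The module is M plus every gene with p strictly below the
threshold (default 0.01); strict inequality makes selection monotone in
the threshold. Markers are always included.

This local scheme deliberately replaces search-engine-style compendium
queries (cross-validated ranking over many curated datasets): it keeps the
same selection rule — rank by coexpression with the markers, keep genes
passing a p cutoff — while making the score and its null fully explicit on
the single compendium at hand. Selection applies a fixed per-gene
threshold with **no multiple-testing correction**, mirroring the original
rule; consequently the expected number of background false positives
grows linearly with background size (≈ t per background gene, e.g.
0.009·n_bg at t = 0.01 with 999 permutations). Recovery precision targets
therefore refer to compendia where the background is at most roughly ten
times the module size; on genome-scale backgrounds the same rule would
need a stricter threshold or an error-rate correction.

## Differential ranking

For a two-class contrast the per-gene score is either the log fold change
(mean case − mean control, data assumed log-scale) or a fixed-prior
moderated t:

    t_g = (mean₁ − mean₀) / ( s̃_g · sqrt(1/n₁ + 1/n₀) ),
    s̃_g² = (d₀·s₀² + d_g·s_g²) / (d₀ + d_g),

with s_g² the pooled within-class variance (d_g = n₁+n₀−2 df), s₀² the
median of the per-gene variances, and d₀ = 4. This is a deliberately
simple variant of empirical-Bayes variance moderation: two documented
constants instead of a fitted hyperprior, enough to stop near-constant
genes from dominating the extremes of the ranking. A gene constant in
both classes scores exactly 0 (zero numerator, positive shrunken
denominator).

The ranked list is direction-tagged; the default is descending (most
up-regulated first), under which disease-like activation gives positive
enrichment and drug-like reversal negative enrichment. Ascending is
exposed because either convention appears in practice and the two are
mirror images under the sign conventions below. Duplicate identifiers
collapse to the score of maximum absolute value (|score| tie → larger
signed value); score ties order lexicographically, so rankings are
reproducible across platforms.

## Enrichment statistic

For a ranked list of N genes and a set S with N_H members present, the
running sum after position i is

    RS(i) = Σ_{j≤i, g_j∈S} |r_j|ᵖ / N_R  −  #{j≤i, g_j∉S} / (N − N_H),

with N_R = Σ_{g_j∈S} |r_j|ᵖ, and the enrichment score ES is the value of
RS at its maximum absolute deviation from zero. ES ∈ [−1, 1] and
RS(N) = 0 exactly (hit and miss mass each sum to one). Weight p = 0 gives
the classic two-sample Kolmogorov–Smirnov deviation between hit and miss
rank distributions (verified exactly against a brute-force two-CDF oracle);
p = 1 — the package default, matching the standard GSEA software — weights
each hit by its score magnitude, emphasizing sets concentrated at the
extremes. If every member score is zero at p = 1 the statistic falls back
to p = 0 with a warning.

Significance uses a gene-tag null: ES values of `n_perm` random sets of
size N_H drawn uniformly without replacement from the list. This is the
appropriate null for a *preranked* list (one differential profile);
phenotype permutation is out of scope. The null is evaluated in
O(n_perm · N_H) after sampling by checking only extremum candidates: the
running sum rises only at hits and falls linearly between them, so its
maximum lies at a hit and its minimum just before a hit or at the final
zero. This shortcut is tested for exact agreement with the full
accumulation on the very sets the null samples.

p-values are signed and add-one: with D the same-sign null values,
p = (1 + #{|d| ≥ |ES|}) / (1 + #D), never displayed as 0; the floor is
1/(#D+1). NES = ES / mean(|D|). The FDR field is computed on the NES scale
with the same guard; for a single gene set it coincides with the nominal p
and is reported separately only to keep the usual ES/FDR report shape.

### Tie and round-off policy

The extremum is chosen by magnitude; a magnitude tie within 1e-12 resolves
to the positive side. The peak is the **first** index attaining the
maximum (positive ES) or the **last** index attaining the minimum
(negative ES), with the same 1e-12 tolerance when several positions tie in
exact arithmetic but differ by round-off. Running sums are clipped to
[−1, 1] to remove 1-ulp overshoot. These choices make ES equal to the
exact-arithmetic KS statistic on every tested instance and make the
leading edge invariant under list reversal whenever the extremum is
unique.

### Leading edge

Positive ES: members at positions ≤ peak; negative ES: members at
positions ≥ peak; ES = 0 (unreachable for non-degenerate inputs) yields an
empty set with a warning. The leading edge is the "core" gene set used in
cross-condition overlap tests.

## Core-gene overlap

Overlap of two core sets within a universe U is tested with the
hypergeometric upper tail P(X ≥ k), X ~ Hypergeom(|U|, |A|, |B|)
(scipy's log-space survival function; exact against subset enumeration to
1e-12). The default universe is the module itself, the smallest defensible
choice when both sets are leading-edge subsets of one module; it is
configurable, and members outside the universe are dropped with a count so
symbol-mapping losses are visible. Note the discrete upper-tail p is
conservative (stochastically ≥ Uniform(0,1)) for small sets; under
independent null contrasts it shows the correct one-sided behaviour (test
level ≤ α) rather than exact uniformity.

## Synthetic data model

A single-latent-factor Gaussian model: per sample a factor f ~ N(0,1);
module genes read β·f + N(0, σ²), background genes N(0, σ²). Module-gene
pairs then have population correlation β²/(β²+σ²), a closed-form target
the generator is tested against. Contrasts drop the factor and add a
signed mean shift δ to a fraction (`effect_fraction`) of module genes in
the case class. All outputs are pure functions of (config, seed) through
fixed named sub-streams.

Defaults encode the two study regimes:

| regime | n_genes | module | samples | β | σ | δ | classes |
|---|---|---|---|---|---|---|---|
| screening contrast | 2000 | 50 | 20+20 | 1.0 | 1.0 | 1.5σ | control/case |
| module recovery    | 500  | 50 | 150   | 1.0 | 0.5 | —   | — |

The recovery regime's β/σ give planted pairwise correlation 0.8; its
background of 450 genes reflects the per-gene-threshold precision argument
above. The screening shift of 1.5 noise-s.d. at n = 20/20 is a strong but
not degenerate block effect (per-gene z ≈ 4.7).

What the generator does **not** emulate: probe-level structure, batch and
platform effects, count-data (RNA-seq) noise, correlated backgrounds,
multiple overlapping modules, and cross-species symbol loss. Passing the
synthetic evaluations therefore shows the machinery is correct and
calibrated under a clean factor model — not that real compendia will yield
modules of any particular size or that real screens will reach these
detection rates.

## Measured operating characteristics

The evaluation battery (also run by `scripts/acceptance.py`) computes, at
the conditions above: exact KS-oracle agreement (1000 instances, N ≤ 50);
type-I error and p-uniformity over 500 null contrasts (n_perm = 499);
detection of up- and down-shifted modules over 100 seeds each; module
recovery precision/recall over 10 seeds (n_null = 999); leading-edge
recall of shift-carrying genes (half the module shifted by 2σ, 20 seeds);
and one seeded end-to-end screen. Problem sizes were chosen once for
p-value resolution (permutation granularity well below the α being
checked) and to keep the battery runnable on a laptop-class single core in
about a minute.

## Known limitations

- The coexpression surrogate scores genes against markers only; it will
  not separate two distinct modules sharing a marker, and its permutation
  null assumes exchangeable samples (no batch structure).
- The fixed-prior moderated t (d₀ = 4, s₀² = median) is not an
  empirical-Bayes fit; with very few genes the median prior is noisy.
- Single-set FDR is the nominal p by construction; multi-set FDR across a
  gene-set collection is not implemented.
- No ortholog mapping: cross-species comparisons rely on case-insensitive
  symbol identity.
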