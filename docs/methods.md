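# Methods

This note records the models behind each pipeline stage, the parameters
that matter, what the synthetic-data generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Orthogroup expansion and contraction

Model: conditional on an orthogroup's total gene count `n` across the
two species groups, the group-A total is Binomial(`n`, `p`) with
`p = |A|/(|A|+|B|)` under the null of no group preference. This treats
each gene as an independent draw and ignores phylogenetic correlation
between species — a deliberate simplification: the test is a screen, not
a birth–death model along a tree.

Both tails are computed exactly through the regularized incomplete beta
function (no normal approximation); an acceptance check verifies
agreement with exact big-integer pmf summation to 1e−12 up to
`n = 10^4`. Orthogroups with `n = 0` in the tested partition are dropped
before adjustment so untestable rows do not inflate the BH family.
BH adjustment is applied separately within the expansion and the
contraction p-value families; separate families are conservative and
symmetric when the direction of a single family is ambiguous.

Call criteria (all configurable): `q < 0.05`; at least 3 of the focal
and 7 of the background species contributing ≥1 gene ("contribution" is
read as the count of species with a nonzero entry); rate ratio
`(S_An/|A|)/(S_Bn/|B|)` strictly above 1 for expansion, below 1 for
contraction. An orthogroup absent from group B counts as ratio = +∞ and
can therefore be called expanded. Expanded and contracted sets are
disjoint by construction.

A simpler two-species rule (`p < 0.05` and count above the cross-species
mean) is provided for pairwise comparisons; it consumes externally
supplied p-values.

## Tandem arrays

A gene joins an array when it is homologous to at least one current
member and lies within `max_intervening` non-member genes of the nearest
member (single linkage, implemented as union–find over rank-windowed
homologous pairs). The default `max_intervening = 0` (strictly
consecutive) matches the MCScanX convention; the parameter is exposed
because published pipelines differ. Homology is symmetrized and
self-hits dropped. Arrays are maximal and disjoint; a windowed
brute-force fixpoint oracle confirms equality on random layouts up to 60
genes.

Shared vs lineage-specific TD genes: a TD gene is shared when its
orthogroup contains TD genes from ≥2 species. Functional-bias
comparisons between species groups use Welch's two-sample t-test on
per-species category percentages (the pooled-variance variant is not
assumed since group variances need not match).

## Collinear blocks and duplication classes

Anchors (homologous gene pairs with chromosome/rank coordinates, scored
by bitscore) are chained by O(n²) dynamic programming per chromosome
pair: chain score = Σ anchor scores − `gap_penalty` × Σ intervening
genes, where the gap between consecutive anchors is
`max(Δrank_a, Δrank_b) − 1` and must not exceed `max_gap`. Ascending
and descending chains are sought separately (descending = inverted
block); the best qualifying chain is extracted greedily, its anchors
removed, and the search repeated, so each anchor lands in ≤1 block.
Defaults: cross-species blocks need >10 genes with gaps <5
(`min_block_genes = 11`, `max_gap = 4`), self-comparison segmental
screens need ≥5 genes. The unit gap penalty is a design choice —
published block finders do not print theirs — and is configurable. Ties
break toward smaller total gap, then lexicographic gene id, making the
output deterministic. Exhaustive subset enumeration verifies optimality
on instances of ≤12 anchors.

Duplicated anchor pairs from a self-comparison are classed per pair:
interchromosomal when the two genes sit on different chromosomes;
tandem when both are known tandem duplicates on one chromosome;
segmental otherwise. The trivial self-diagonal is removed.

Fusion counting from an ancestral-karyotype painting: after discarding
painted blocks below `min_block_genes`, each modern chromosome
contributes (distinct ancestral labels − 1); the sum is a lower bound on
fusions. On a one-to-one painting of 21 ancestral groups over 12
chromosomes this reduces to the identity 21 − 12 = 9.

## NG86 Ka/Ks

Synonymous sites per codon: at each position, (number of synonymous
single-base changes)/3, with changes to stop codons counted as
nonsynonymous; `S` is averaged over the two sequences, and `S + N`
equals the alignment length exactly. Differences for codons differing at
`d` positions average over all `d!` single-substitution pathways with
equal weights; pathways through a stop codon are excluded and weights
renormalized (if every pathway crosses a stop — possible only for
`d ≥ 2` — all are kept rather than dropping the codon). Jukes–Cantor
correction is applied to `pS = Sd/S` and `pN = Nd/N`; proportions
≥ 3/4 flag the estimate saturated and leave the rate undefined.
Estimates are symmetric in the two sequences.

Ks distributions are summarized as a histogram over `(0, ks_max]` plus
the local maxima of a Gaussian KDE (Silverman bandwidth by default,
because duplication peaks are read off a smoothed density); each mode is
reported with the share of observations nearest to it.

## LTR insertion ages

`T = K/(2μ)` with `K` the JC-corrected p-distance over alignable columns
(gap and ambiguous columns excluded from numerator and denominator).
`μ` has units substitutions·site⁻¹·year⁻¹ and has **no default**: rates
in plants span roughly 1e−9 to 2e−8 and the choice dominates the answer,
so the CLI refuses to run without it and records it in the output.
Burst summaries report the KDE modal age and 5/50/95% quantiles.

## Diel analysis

Expression is prefiltered to genes whose replicate-mean FPKM strictly
exceeds 1 at ≥1 timepoint. Rhythmicity: OLS of `log2(FPKM+1)` on
{t, t², t³} (time standardized for conditioning; the basis span, and
hence the F statistic, is unchanged) over all 27 replicate points,
F-test against the intercept-only model, BH across genes. Genes with
zero variance are flagged degenerate with p = 1. The duplicated 18:00
endpoint is kept as two design points, mirroring the sampling scheme.
The log transform is exposed in config.

Clustering: mean profiles are z-scored per gene; distance is 1 − Pearson
correlation; agglomerative average linkage cut at k = 9. Average linkage
and correlation distance are package choices where only "hclust" is
conventionally specified; both are configurable. Labels are renumbered
by first appearance so the partition is independent of gene order.

Cross-species classification uses mean profiles (replicate-level
correlation is noisier and the convention is not fixed; the choice is
recorded here). A gene is *divergent* when both Pearson and Spearman
against the C3 reference are < 0.5, and a *strong CAM candidate* when it
is divergent and both coefficients against the CAM reference are > 0.8;
otherwise *conserved*; undefined coefficients give *degenerate*. The
"both coefficients" conjunction can be relaxed to Pearson-only in
config.

## Motif scanning and enrichment

Scanning is exact degenerate-consensus matching over the IUPAC alphabet;
all five shipped circadian elements are short consensus strings, for
which log-odds scanning at a stringent p-value threshold reduces to
(near-)exact matching, so a full PWM engine is deliberately not used. A
per-window mismatch allowance (default 0) is exposed. Default strand
policy scans both strands with palindromes (CACGTG) counted once per
position. Enrichment uses presence/absence (≥1 occurrence) 2×2 Fisher
exact tests per motif between two gene groups with BH across motifs —
presence/absence is robust to promoter-length effects.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of spec + seed (byte-identical reruns) and
serialize a truth record sufficient to score sensitivity and FDR.

- Count matrices: Poisson(λ = 2) background per species (the simplest
  null with a tunable mean; real orthogroup counts are overdispersed and
  phylogenetically correlated, which this does not emulate), planted
  orthogroups multiply the focal-group mean by `fold_effect` (default 4,
  a clearly detectable but not trivial effect at λ = 2). Default shape
  5 + 13 species, 2000 orthogroups, 5% planted.
- Genome layouts: uniformly spaced genes (1 kb genes every 2.5 kb) on a
  small number of chromosomes; planted tandem arrays become cliques of
  self-hits, planted collinear blocks become rank-aligned (optionally
  inverted) anchor chains; optional uniform noise hits. Real gene
  spacing, local duplication gradients and fractionation are not
  modeled — passing closed loops shows the detectors invert the planted
  structure, not that they are robust to assembly artifacts.
- Codon pairs: random stop-free CDS with exactly the requested number of
  synonymous and nonsynonymous single-base changes, at most one per
  codon, so NG86 difference counts are exactly recoverable; multi-hit
  codons are exercised separately by randomized tests.
- Diel profiles: `FPKM = exp(b + a·cos(2π(t−φ)/24) + ε)` with lognormal
  noise (keeps FPKM positive), phases drawn from {0, 6, 12, 18} h after
  the 18:00 start, baseline `b ~ U(1, 3)` on the log scale, defaults
  30% rhythmic at amplitude 1 and noise SD 0.25. Real diel data have
  non-sinusoidal waveforms and shared-day covariance that this ignores.
- Promoters: i.i.d. uniform ACGT background with motif copies planted
  without overlap at recorded positions; real promoter base composition
  is neither uniform nor independent.
- LTR pairs: per-site mutation probability set to the JC expectation
  `(3/4)(1 − e^{−8μT/3})` at the planted age so the JC estimator is
  unbiased by construction; insertion-site preference and gap evolution
  are not modeled.

## Problem sizes and numerical choices

The shipped test and acceptance runs use: 5000 orthogroups × 20 runs for
null calibration and 2000 × 5 runs for recovery; 2000 genes for the
rhythmicity type-I rate (Gaussian noise on the regression scale, where
the F-test null is exact) and 4 × 500 genes for power; 10 replicates of
200 + 200 promoters (300 bp) for enrichment power; 1000 codon-pair and
LTR instances; 500 + 500 Ks values for mixture-mode recovery. These
sizes give stable two-decimal metrics while keeping a full run in the
minutes range on one core.

Ties and degenerate inputs: empty inputs return empty results (not
errors) wherever a downstream stage can proceed; zero-variance profiles,
saturated substitution proportions, and both-groups-constant t-tests are
flagged rather than guessed at. All randomness flows from a single seed
recorded in every output header.

## Known limitations

The expansion test ignores phylogeny (a CAFÉ-style birth–death model is
out of scope by design). Block chaining is O(n²) per chromosome pair —
fine at study scale, not tuned for all-vs-all mammalian genomes. The
rhythmicity F-test assumes homoscedastic Gaussian residuals on the
transformed scale and does not model autocorrelation between adjacent
timepoints. Motif enrichment conditions on promoter sets being
comparable in length and composition between groups.
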