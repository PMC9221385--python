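# Methods

## Signature derivation

The core statistic is the per-bait co-expression set. For bait *b* and gene
*g* over *n* samples, Pearson's *r* is computed on log₂-scale values
(vectorized over genes) and its two-sided p-value from the exact
t-transform *t = r·√((n−2)/(1−r²))* with *n−2* degrees of freedom. The
t-transform was chosen over permutation because it is deterministic and is
the standard for transcriptome-wide co-expression screens; it assumes
bivariate normality on the log scale, which log₂ expression approximates
well away from the detection floor. Genes pass for a bait when
*r > r_threshold* (default 0.4) and *p < p_threshold* (default 0.001);
with `direction="positive_only"` the sign filter is implied by the positive
r-threshold, which is how "upregulated co-expressed genes" is
operationalized. `direction="both"` filters on |r| instead.

No multiple-testing correction is applied inside the per-bait screen: the
overlap filter across baits is itself the specificity mechanism (a
background gene must clear *r* and *p* thresholds for ≥ *k_min* independent
baits), and the null-control test verifies that with 10 baits, *k* ≥ 5,
*r* > 0.4, *p* < 0.001 and 150 samples, background leakage into the
signature is essentially zero. BH correction is applied where individual
significance claims are made: group contrasts, bait-consistency ranking,
and collection enrichment.

Member order is (descending overlap count, lexicographic gene id), so a
signature is byte-reproducible. Baits are excluded from signature
membership (they are inputs, not discoveries) but may appear in other
baits' passing sets. Zero-variance genes are excluded from correlation with
a logged warning rather than failing the run; the z-score stage carries
them as flagged zero rows instead so panels keep their shape.

## Gene-set overlap statistics

Overlap significance is the hypergeometric upper tail
P(X ≥ |sig ∩ ref|) with X ~ Hypergeom(|U|, |ref|, |sig|); only
over-representation is tested. The universe *U* is a mandatory, logged
parameter (default in the pipeline: all genes of the analyzed matrix) —
the union-coverage fraction and the tail probabilities are meaningless
without stating it. Union coverage is |sig ∩ ∪refs| / |sig|, i.e. genes of
the query found in *any* reference.

## Group contrasts

z-scores are per gene over **all** samples (tumor and normal pooled), with
sample standard deviation (ddof = 1, configurable). Group-vs-reference
comparisons use the two-sided Mann–Whitney test (asymptotic, with
continuity correction) — robust to the heavy tails of z-scored expression;
Welch's t is available as an option. BH adjustment is applied across genes
within one group comparison, not across comparisons jointly, matching the
per-panel way such contrasts are usually reported. Direction is the sign of
the median z difference.

The 2×2 association test is Fisher's exact with the point-probability
two-sided convention (sum of all point probabilities ≤ the observed
table's); conventions differ between tools, so this one is stated here and
cross-checked in the tests against exact rational-arithmetic enumeration.
The conditional odds ratio is reported, NaN when a margin is zero. R×C
tables fall back to the chi-squared test without an odds ratio.

Signature genes are clustered by average-linkage hierarchical clustering on
correlation distance (1 − r between gene z-rows), cut at *k* clusters
(default 2, the cluster-A/cluster-B structure of pseudohypoxia signatures);
genes are sorted before clustering so the partition is independent of input
order.

## Embedding and segregation score

Samples are embedded with t-SNE (PCA initialization, auto learning rate)
on the signature-restricted z-matrix, Euclidean distance. Perplexity
defaults to 10, sized for PPGL-scale cohorts of ~100–200 samples; the seed
is mandatory and recorded, and the embedding is deterministic given it.
"Segregation" is operationalized as the mean silhouette coefficient on the
2-D coordinates for (a) pseudohypoxic (VHL/SDH/EPAS1) vs all other samples
and (b) VHL vs SDH+EPAS1 vs other; normal-tissue samples fall into
"other" in both partitions. Because t-SNE distorts global geometry, the
silhouette on the high-dimensional z-matrix is reported alongside each 2-D
score.

## Synthetic data generator

All on log₂ scale:

```
x[g, s] = baseline[g] + loading[g] · factor[s] + effect[g, group(s)] + ε,
ε ~ N(0, noise_sd)
```

* `baseline[g] ~ N(8, 2)` — typical array/RNA-seq log₂ magnitudes; only the
  scale plausibility matters, baselines cancel in correlations and
  z-scores.
* `factor[s]` — the latent hypoxia-program activity: unit-variance noise
  plus a mean shift of `pseudohypoxia_factor_shift` (default 1.0 SD) in
  VHL/SDH/EPAS1 samples, then standardized by its theoretical moments to
  cohort mean 0 / variance 1. The shift is what makes module expression
  higher in pseudohypoxic tumors — constitutive pathway activation is the
  defining feature being emulated. 1.0 was fixed by model algebra: it keeps
  the expected cross-correlation between genotype-effect panels and baits
  near 0.26, safely below the 0.4 threshold (so the signature stays the
  co-expression module), while giving ~0.8 within-group SD of separation
  per module gene, enough for the embedding to segregate pseudohypoxic
  samples.
* Bait and module genes carry `loading = √(module_r/(1−module_r))·noise_sd`
  on the shared factor, so any bait–module pair has Pearson correlation
  exactly `module_r` (default 0.7). One shared factor is used for all baits
  and module genes because the baits are themselves co-expressed hypoxia
  targets.
* HIF1α-panel genes get `+hif1_effect` (default +2 log₂) in VHL samples
  only; HIF2α-panel genes `+hif2_effect` in VHL, SDH and EPAS1 — the
  genotype-specific target-activation pattern of pseudohypoxic PPGL.
* Background genes are independent noise.

Defaults: 500 genes, 10 baits, 50-gene module, 20 + 20 target panels, 30
samples in each of the five groups (150 total), unit residual SD. The
generator is deterministic given the seed and emits disjoint ground-truth
role sets.

What the generator does **not** emulate: count noise / mean–variance
coupling, library-size and batch effects, correlated background structure
(pathways other than the planted module), missing values, or symbol
aliasing. A green recovery test therefore establishes that the derivation
logic is correct under the factor-model world, not that a real cohort's
normalization choices are handled.

## Numerical choices and degenerate inputs

* Log transform: log₂(x + 1) by default, pseudocount configurable;
  applying it to an already-log₂ matrix is a contract error rather than a
  silent double transform.
* r is clipped to [−1, 1] after the vectorized computation; |r| = 1 maps to
  p = 0 exactly.
* Empty signatures are legal (no error); recovery precision on an empty
  signature is reported as 0 with a warning.
* Ties in member ordering and in consistency ranking break
  lexicographically.
* `min_overlap_k` greater than the number of baits is an error.
* Silhouettes are NaN when a partition has fewer than two populated
  classes.

## Known limitations

* Pearson on log₂ values is the only correlation currently wired into the
  bait screen (Spearman is a planned option); heavy outliers in poorly
  normalized data will inflate r.
* The pan-cancer bait-consistency ranking implements a defensible reading
  (one-sided rank-sum per dataset, BH across candidates, count of
  significant datasets) of a procedure whose original appendix-level
  details are not public; its provenance block labels it as such.
* The union-coverage statistic counts genes found in *any* reference
  signature; averaging pairwise overlaps would give different numbers.
* t-SNE parameters other than perplexity and seed are library defaults and
  are recorded in provenance, not tuned.
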