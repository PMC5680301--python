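# Methods

`pharmclust` classifies cancer cell lines from transcriptome profiles,
checks that two independently profiled panels of the same lines arrive at
the same grouping, and asks whether the resulting clusters separate drug
responses better than tissue of origin does. This note records the model,
the statistics, and the numerical choices, in the package's own terms.

## Problem setting

Two studies profile an overlapping panel of cell lines: each provides a
genes × samples log-expression matrix, a drugs × samples response table
(micromolar IC50, AUC, or mean viability), and optionally binary mutation
calls and tissue annotations. A scored gene–gene functional interaction
network (combined scores in [0, 1]) is shared. The analysis must be
unsupervised, reproducible to the byte given a seed, and comparable
across the two datasets despite batch effects and different gene panels.

## Gene selection: IQR inflexion point

Per-gene variability is the interquartile range (Q3 − Q1, linear-
interpolation quantiles; at least 4 samples required). Sorting the IQRs
ascending gives a concave curve; after min–max normalizing both axes to
[0, 1], the inflexion (knee) point is the index with maximum
perpendicular distance to the chord joining the curve's endpoints. Ties
go to the larger index, and only genes with IQR strictly above the knee
value are kept — both choices err toward fewer, more variable genes. A
flat profile (all IQRs equal) has no knee and raises an error suggesting
a fixed-fraction cutoff instead.

## Consensus clustering

Stability-based clustering of either axis of the expression matrix:

1. Each iteration subsamples 80% of the *features* (samples when
   clustering genes, genes when clustering cell lines).
2. Items are clustered by complete-data Pearson distance (1 − r) and
   Ward linkage, cut at each candidate k.
3. The consensus matrix for k records the fraction of iterations in
   which each item pair landed in the same cluster.
4. The final partition at k comes from average-linkage clustering of
   1 − consensus.

1000 iterations by default (100 in the fast profile used by tests). A
zero-variance item is reported by name up front rather than producing
NaN distances mid-run.

**Choosing k.** The default criterion keeps the largest k whose consensus
matrix is still crisp: the fraction of entries in the ambiguous band
(0.1, 0.9) must not exceed a tolerance (0.02). If no k qualifies, the
smallest candidate is returned and the result is flagged
`weak_structure`. The classical delta-area criterion (relative increase
of the consensus CDF area) is available as an option but tends to
overshoot: ever-crisper partitions keep shrinking the mean consensus, so
area gains stay above the tolerance well past the true k. Note the
stability criterion can also exceed a planted k when small subgroups
split off with perfect stability — the headline grouping is unaffected
(high adjusted Rand index, high cross-dataset accuracy) but the chosen k
should be read as "number of stable groups", not a point estimate of the
true cluster count. Both criteria can be bypassed with an explicit k.

## Network filtering of gene modules

Gene modules (gene-axis consensus clusters) are pruned in two passes
against the interaction network:

1. Keep genes with at least one edge of combined score ≥ 0.7 to another
   gene of the same module. Connected components of the kept genes form
   candidate networks; singletons are dropped.
2. Within each component, keep genes whose mean Pearson correlation to
   the other members is ≥ 0.5 (a max-correlation rule is available).

Both thresholds are inclusive and configurable. The surviving union of
genes is the feature set for cell-line clustering, so the final grouping
rests only on co-expressed genes with independent interaction support.

## Cross-dataset concordance

For cell lines clustered in both datasets, a pairwise similarity matrix
counts in how many datasets each pair co-clusters (0, 1, or 2). The
headline accuracy is (#pairs counted twice) / (#pairs counted at least
once) — a Jaccard-style score that ignores the uninformative mass of
pairs separated in both datasets; a Rand-style variant over all pairs is
also reported. Cluster labels are matched across datasets by Hungarian
assignment on the contingency table; robust findings must refer to
matched clusters.

## Drug-response analysis

All metrics are mapped to one "high = sensitive" scale: micromolar IC50
x → −log10(x · 10⁻⁶) (so 1 μM → 6 and a 10-fold potency gain adds 1);
mean viability v → 1 − v; AUC passes through, flipped if high values
mean resistance. Nonpositive IC50s are rejected by name.

**Partition comparison.** The pseudo-F of a drug under a partition is
the Calinski-Harabasz ratio (between-SS/(K−1)) / (within-SS/(N−K)) after
listwise deletion of missing responses. A variant with transposed
degrees of freedom is reported alongside for comparability with the
older convention. Per drug, the expression-derived clustering and the
tissue partition are compared; a paired t test across drugs summarizes
which partition separates responses better. Perfect separation
(within-SS = 0) is flagged infinite; fully constant responses score 0.

**Associations.** Each (drug, cluster) pair gets a Welch t test of the
cluster versus all remaining lines (groups of < 3 skipped, logged), BH
adjustment within each drug (a global family option exists), phenotype
"sensitive" iff t > 0, significance at adjusted p < 0.05. Robust
associations are significant in both datasets with matched clusters and
the same phenotype.

## Cluster characterization

- **Differential expression**: per-gene Welch t, cluster vs rest,
  ranked by signed t (an equal-variance option exists).
- **Pre-ranked gene-set enrichment**: weighted running sum over the
  ranked list (hits advance ∝ |t|, misses retreat uniformly); ES is the
  extremum; significance from gene-label permutations with a
  sign-matched, add-one p; NES normalizes by the mean |ES| of same-sign
  permutations.
- **Mutation enrichment**: one-tailed Fisher exact (over-representation
  inside the cluster), p = 1 for genes never mutated, BH across all
  (gene, cluster) pairs jointly.
- **EMT classification**: signature genes are z-scored, cell lines are
  Pearson/Ward-clustered into three groups, and each group is labelled
  epithelial or mesenchymal only if the mean difference between up- and
  down-signature scores clears a margin (0.5); at least half the
  signature must be present in the panel.
- **Receptor subtypes**: each marker gene (ESR1, PGR, ERBB2) gets a
  two-component Gaussian mixture; a gene is called bimodal only if the
  two-component fit beats one component by BIC *and* both components
  hold ≥ 2 samples — otherwise everything is negative for that gene,
  with a warning. Without the BIC guard, a mixture happily splits
  unimodal data into two overlapping halves and fabricates positives.
  Precedence: Her2+ (ERBB2-positive), then ER+Her2−, then triple
  negative, else "other".

## Synthetic data generator

A first-class component, not a test fixture: it emulates two studies
profiling the same cell-line panel.

- Module genes share a cluster-specific ±shift pattern (baseline
  N(7, 1), shift 3 × noise SD by default); decoy genes are pure noise.
  The module × cluster sign patterns come from a binary cluster code
  extended with a parity bit and complement bits, so any two clusters
  differ in at least two modules (hence the requirement that the number
  of modules exceed the code width).
- Dataset B shares the planted means but adds a per-gene batch offset
  (SD 0.5) and independent noise; gene panels overlap by 90%.
- The interaction graph connects module genes with high scores (ring
  backbone plus random extras, scores ≥ 0.9 by default) and sprinkles
  sparse low-score edges elsewhere, below the 0.7 pruning threshold.
- Drug responses are drawn on the −log10(M) sensitivity scale with one
  affected cluster per drug (±2 SD by default), then inverted to
  micromolar IC50s; the two tables mask 25% and 45% of entries,
  mirroring the typical asymmetry of dose-response fit failures.
- Mutations are Bernoulli (base rate 0.1) with an 8-fold odds increase
  in one cluster per mutation gene.

What it deliberately does *not* emulate: dose-response curve fitting
(IC50s are drawn directly), gene-length or library-size artifacts of raw
RNA-seq counts (values are already log-scale expression), correlated
noise between drugs, and tissue-driven expression structure (tissue
labels are random, which is exactly what makes them a useful null for
the partition comparison).

Every generator function is a pure function of (config, seed), and the
returned truth bundle records all planted structure for scoring.

## Determinism and error handling

All randomness flows through explicit seeds (`numpy.random.default_rng`);
running the file-based pipeline twice on identical inputs produces
byte-identical outputs, and the output directory includes a provenance
file with input checksums and the full configuration. Pipeline stages
wrap errors with the stage name; input validation errors name the
offending gene, sample, or parameter.
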