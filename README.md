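# pharmclust

Transcriptome-driven classification of cancer cell lines and analysis of
its relationship to drug sensitivity.

Large cell-line panels are profiled independently by different
laboratories: same cells, different expression platforms, drug assays,
and metrics. `pharmclust` clusters the cell lines of each dataset from
expression alone — keeping only variable genes whose co-expression is
backed by a functional interaction network — then quantifies whether the
two datasets agree on the grouping, and whether the grouping explains
drug response better than tissue of origin does. A synthetic-data
generator that emulates such paired panels with known planted structure
is part of the package, so every claim can be checked against ground
truth.

## What it does

1. **Gene selection** — rank genes by interquartile range and cut at the
   inflexion point of the sorted curve (maximum distance to the chord).
2. **Gene modules** — subsampled consensus clustering (Pearson distance,
   Ward linkage) of the selected genes.
3. **Network filter** — keep module genes with an interaction partner at
   combined score ≥ 0.7 in the same module, then require mean Pearson
   r ≥ 0.5 within each connected component.
4. **Cell-line clustering** — consensus clustering of samples on the
   surviving genes; k chosen by consensus-matrix crispness.
5. **Concordance** — pairwise co-clustering counts across the two
   datasets (0/1/2), accuracy as co-clustered-pair agreement, and
   Hungarian matching of cluster labels.
6. **Drug associations** — all response metrics mapped to a common
   "high = sensitive" scale; pseudo-F comparison of clustering vs tissue
   partitions; cluster-vs-rest Welch t tests with Benjamini-Hochberg
   FDR; intersection of associations that replicate in both datasets.
7. **Characterization** — differential expression, pre-ranked gene-set
   enrichment, Fisher mutation enrichment, EMT signature classification,
   and Gaussian-mixture receptor-status calls.

See [docs/methods.md](docs/methods.md) for the statistical details and
numerical choices.

## Worked example

Generate a paired synthetic study and run the complete analysis
(`examples/02_full_study.py`):

```python
from pharmclust import AnalysisConfig, GeneratorConfig, generate_bundle, run_study

bundle = generate_bundle(GeneratorConfig(
    n_genes=500, n_decoy_genes=120, n_samples=150,
    n_modules=4, n_clusters=5, n_drugs=8, seed=3,
))
study = run_study(
    bundle["expression_a"], bundle["expression_b"], bundle["graph"],
    AnalysisConfig(n_iterations=100, seed=0),
    drugs_a=bundle["drugs_a"], drugs_b=bundle["drugs_b"],
    mutations=bundle["mutations"], tissues=bundle["truth"].tissue_labels,
)
```

Output:

```
dataset A: 330 variant genes -> 3 modules -> 330 after network filter -> 12 cell-line clusters (ARI vs planted: 0.910)
dataset B: 328 variant genes -> 3 modules -> 328 after network filter -> 12 cell-line clusters (ARI vs planted: 0.909)
cross-dataset accuracy (co-clustered pairs): 0.961
cross-dataset accuracy (all pairs):          0.993
10 drug-cluster associations replicate in both datasets:
drug_id cluster_a cluster_b phenotype
 drug01       C11       C11 resistant
 drug02       C11       C11 resistant
 drug03       C12       C12 sensitive
 ...
```

The two pseudo-datasets share cell lines but differ in noise, batch
offsets, and gene panels — yet 96% of the pairs co-clustered in one
dataset co-cluster in the other, and the drug effects planted in the
generator are rediscovered independently in both and intersect. (The
chosen k exceeds the planted 5 because consensus clustering splits off
small but perfectly stable subgroups; the adjusted Rand index of 0.91
against the planted partition shows the main grouping is intact.)

The other example scripts are smaller single-topic walks:

- `examples/01_simulate_and_cluster.py` — gene selection and cell-line
  consensus clustering, ARI 1.000 against the planted clusters.
- `examples/03_drug_associations.py` — metric harmonization (IC50
  10/1/0.1 μM → sensitivity 5/6/7), association tests, and the pseudo-F
  comparison (clusters beat tissue of origin for 100% of drugs,
  paired t = 4.96).
- `examples/04_characterization.py` — differential expression, GSEA
  (module ES = +1.00, p = 0.0022), mutation enrichment (8/12 vs 2/28,
  adjusted p = 4.6e-04), EMT and receptor-subtype calls.

## Command line

Every step is also available as a subcommand:

```sh
pharmclust simulate --out data/ --seed 5 --n-samples 150
pharmclust run --expression-a data/expression_a.tsv \
               --expression-b data/expression_b.tsv \
               --graph data/interactions.tsv \
               --drugs-a data/drugs_a.tsv --drugs-b data/drugs_b.tsv \
               --out results/
pharmclust select-genes --expression data/expression_a.tsv --out iqr.tsv
pharmclust cluster --expression data/expression_a.tsv --k-range 2-12 --out clusters.tsv
pharmclust concordance --clustering-a a.tsv --clustering-b b.tsv
pharmclust associate --drugs data/drugs_a.tsv --clustering clusters.tsv --out assoc.tsv
```

All commands are deterministic given `--seed`; `run` writes every result
table plus a provenance file with input checksums.

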