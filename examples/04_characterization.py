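"""Characterize clusters: differential expression, gene-set enrichment,
mutation enrichment, and signature-based phenotype calls.

Builds a small panel by hand so every planted signal is visible in the
output: one cluster over-expresses a gene module and carries an enriched
mutation; a separate expression matrix carries an epithelial/mesenchymal
split and bimodal receptor genes.
"""

import numpy as np
import pandas as pd

from pharmclust import (
    CellLineClustering,
    ExpressionMatrix,
    GeneModule,
    MutationMatrix,
    call_breast_subtypes,
    classify_emt,
    differential_expression,
    mutation_enrichment,
    preranked_gsea,
)

rng = np.random.default_rng(0)
samples = [f"CL{i:02d}" for i in range(40)]
clusters = CellLineClustering(
    sample_ids=tuple(samples),
    labels=tuple("C1" if i < 12 else "C2" for i in range(40)),
)

# 60 genes; the first 10 form a module over-expressed in cluster C1
genes = [f"g{i:02d}" for i in range(60)]
arr = rng.normal(5.0, 1.0, size=(60, 40))
arr[:10, :12] += 2.0
expr = ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))

ranked = differential_expression(expr, clusters, "C1")
top = ranked[0]
print(f"top C1 gene: {top.gene_id} (t = {top.t_statistic:+.2f}, "
      f"p = {top.p_value:.2e})")

module = GeneModule("module1", frozenset(genes[:10]))
gsea = preranked_gsea(ranked, module, n_permutations=500, seed=1)
print(f"module1 in C1: ES = {gsea.es:+.2f}, NES = {gsea.nes:+.2f}, "
      f"p = {gsea.p_value:.4f} ({gsea.direction})")

# a mutation carried by 8 of 12 C1 lines but only 2 of 28 others
mut_row = [int(i < 8 or i in (20, 30)) for i in range(40)]
mut = MutationMatrix(pd.DataFrame([mut_row], index=["KRAS"], columns=samples))
hit = [r for r in mutation_enrichment(mut, clusters) if r.cluster == "C1"][0]
n_in = hit.mutated_in + hit.unmutated_in
n_out = hit.mutated_out + hit.unmutated_out
print(f"KRAS in C1: {hit.mutated_in}/{n_in} vs "
      f"{hit.mutated_out}/{n_out}, adjusted p = {hit.adjusted_p:.2e}")

# epithelial/mesenchymal split on a signature of up and down genes
up = {f"up{i}" for i in range(20)}
down = {f"dn{i}" for i in range(20)}
sig_arr = rng.normal(0.0, 1.0, size=(40, 40))
sig_arr[:20, :15] += 2.0   # up-genes high in the first 15 lines
sig_arr[20:, :15] -= 2.0   # down-genes low in the same lines
sig_expr = ExpressionMatrix(pd.DataFrame(
    sig_arr, index=sorted(up) + sorted(down), columns=samples))
calls = classify_emt(sig_expr, up, down)
counts = pd.Series([c.label for c in calls]).value_counts()
print("EMT calls:", {k: int(v) for k, v in counts.items()})

# receptor-status calls from bimodal expression of three marker genes;
# PGR is deliberately unimodal here, which triggers a warning and an
# all-negative call for that gene
rec = rng.normal(4.0, 0.4, size=(3, 40))
rec[0, :10] += 4.0          # ESR1 high in 10 lines
rec[2, 10:16] += 4.0        # ERBB2 high in 6 other lines
rec_expr = ExpressionMatrix(pd.DataFrame(
    rec, index=["ESR1", "PGR", "ERBB2"], columns=samples))
subtypes = pd.Series(
    [c.label for c in call_breast_subtypes(rec_expr)]).value_counts()
print("receptor subtypes:", {k: int(v) for k, v in subtypes.items()})
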