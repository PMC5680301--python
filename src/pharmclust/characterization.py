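"""Cluster characterization: differential expression, module GSEA,
mutation enrichment, EMT status and breast-cancer receptor subtypes.

The cluster-vs-rest transcriptomic contrast uses a per-gene two-group
comparison of means (Welch t by default); genes ranked by the signed t
statistic feed a pre-ranked gene-set enrichment analysis of the gene
modules.  Mutation enrichment is a one-tailed Fisher exact test per
(gene, cluster) with Benjamini-Hochberg adjustment across all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    CellLineClustering,
    ExpressionMatrix,
    GeneModule,
    MutationMatrix,
)

__all__ = [
    "DeResult", "GseaResult", "EnrichmentResult", "EmtCall", "SubtypeCall",
    "differential_expression", "preranked_gsea", "mutation_enrichment",
    "classify_emt", "call_breast_subtypes", "gsea_enrichment_score",
]


@dataclass(frozen=True)
class DeResult:
    gene_id: str
    t_statistic: float
    p_value: float
    cluster: str
    rank: int  # 0 = most positively cluster-associated


@dataclass(frozen=True)
class GseaResult:
    module_id: str
    cluster: str
    es: float
    nes: float
    p_value: float
    direction: str  # "up" | "down"


@dataclass(frozen=True)
class EnrichmentResult:
    gene_id: str
    cluster: str
    mutated_in: int
    unmutated_in: int
    mutated_out: int
    unmutated_out: int
    p_value: float
    adjusted_p: float = float("nan")


@dataclass(frozen=True)
class EmtCall:
    sample_id: str
    label: str  # "epithelial" | "mesenchymal" | "neither"


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    label: str  # "TN" | "ER+Her2-" | "Her2+" | "other"


def differential_expression(
    expr: ExpressionMatrix,
    clustering: CellLineClustering,
    cluster: str,
    equal_var: bool = False,
) -> list[DeResult]:
    """Cluster-vs-rest two-group comparison of mean expression per gene.

    Returns one record per gene, ranked by signed t statistic in
    descending order (positive t = higher in the cluster).  Welch
    (unequal-variance) statistics by default; set ``equal_var`` for the
    pooled-variance form.
    """
    members = set(clustering.members(cluster))
    if not members:
        raise ValueError(f"cluster {cluster!r} not present in clustering")
    in_cols = [s for s in expr.sample_ids if s in members]
    out_cols = [s for s in expr.sample_ids if s not in members]
    if len(in_cols) < 2 or len(out_cols) < 2:
        raise ValueError(
            f"insufficient replicates for cluster {cluster!r}: "
            f"{len(in_cols)} in, {len(out_cols)} out (need >= 2 each)"
        )
    x_in = expr.values[in_cols].to_numpy(dtype=float)
    x_out = expr.values[out_cols].to_numpy(dtype=float)
    t, p = stats.ttest_ind(x_in, x_out, axis=1, equal_var=equal_var)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    order = np.argsort(-t, kind="stable")
    results = []
    for rank, idx in enumerate(order):
        results.append(DeResult(
            gene_id=expr.gene_ids[idx],
            t_statistic=float(t[idx]),
            p_value=float(p[idx]),
            cluster=cluster,
            rank=rank,
        ))
    return results


def gsea_enrichment_score(
    scores: np.ndarray, is_member: np.ndarray, weight: float = 1.0
) -> float:
    """Weighted Kolmogorov-Smirnov-like running-sum enrichment score.

    ``scores`` are the ranking statistics in ranked order (best first);
    ``is_member`` flags the gene-set members.  Hits advance the running
    sum proportionally to |score|^weight, misses retreat uniformly; the
    ES is the extremum (largest absolute excursion) of the walk.
    """
    scores = np.asarray(scores, dtype=float)
    is_member = np.asarray(is_member, dtype=bool)
    n = len(scores)
    n_hit = int(is_member.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must be a proper non-empty subset of the list")
    w = np.abs(scores) ** weight
    hit_total = w[is_member].sum()
    if hit_total == 0:  # all member scores are exactly 0
        hit_steps = np.where(is_member, 1.0 / n_hit, 0.0)
    else:
        hit_steps = np.where(is_member, w / hit_total, 0.0)
    miss_steps = np.where(is_member, 0.0, 1.0 / (n - n_hit))
    walk = np.cumsum(hit_steps - miss_steps)
    return float(walk[np.argmax(np.abs(walk))])


def preranked_gsea(
    ranked: list[DeResult],
    module: GeneModule,
    n_permutations: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> GseaResult:
    """Pre-ranked GSEA of one gene module against a ranked gene list.

    The null distribution comes from permuting which ranks are module
    members; the p-value and normalized ES are computed against permuted
    scores with the same sign as the observed ES, keeping the p-value in
    (0, 1] via the add-one rule.
    """
    ranked = sorted(ranked, key=lambda r: r.rank)
    gene_ids = [r.gene_id for r in ranked]
    absent = module.gene_ids - set(gene_ids)
    if absent:
        raise ValueError(f"module genes missing from ranking: {sorted(absent)[:5]}")
    scores = np.array([r.t_statistic for r in ranked])
    is_member = np.array([g in module.gene_ids for g in gene_ids])
    es = gsea_enrichment_score(scores, is_member, weight)

    rng = np.random.default_rng(seed)
    n_hit = int(is_member.sum())
    n = len(scores)
    perm_es = np.empty(n_permutations)
    flags = np.zeros(n, dtype=bool)
    for i in range(n_permutations):
        flags[:] = False
        flags[rng.choice(n, size=n_hit, replace=False)] = True
        perm_es[i] = gsea_enrichment_score(scores, flags, weight)

    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    n_extreme = int((np.abs(same_sign) >= abs(es)).sum())
    p = (n_extreme + 1) / (len(same_sign) + 1)
    mean_same = float(np.abs(same_sign).mean()) if len(same_sign) else np.nan
    nes = es / mean_same if mean_same and mean_same > 0 else np.nan
    return GseaResult(
        module_id=module.module_id,
        cluster=ranked[0].cluster,
        es=es,
        nes=float(nes),
        p_value=float(p),
        direction="up" if es >= 0 else "down",
    )


def mutation_enrichment(
    mut: MutationMatrix, clustering: CellLineClustering
) -> list[EnrichmentResult]:
    """One-tailed Fisher enrichment of each mutation in each cluster.

    Tests whether the mutation is over-represented inside the cluster
    relative to all remaining cell lines combined; BH adjustment is
    applied jointly across all (gene, cluster) pairs.  A gene never
    mutated anywhere gets p = 1 by convention.
    """
    shared = [s for s in mut.sample_ids if s in set(clustering.sample_ids)]
    if not shared:
        raise ValueError("no samples shared between mutations and clustering")
    lab = clustering.as_series().loc[shared]
    m = mut.values[shared]
    records: list[EnrichmentResult] = []
    for cluster in clustering.cluster_labels():
        in_mask = (lab == cluster).to_numpy()
        if not in_mask.any():
            continue
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        for gene in mut.gene_ids:
            row = m.loc[gene].to_numpy()
            a = int(row[in_mask].sum())        # mutated, in cluster
            c = int(row[~in_mask].sum())       # mutated, outside
            if a + c == 0:
                p = 1.0
            else:
                _, p = stats.fisher_exact(
                    [[a, n_in - a], [c, n_out - c]], alternative="greater"
                )
            records.append(EnrichmentResult(
                gene_id=gene, cluster=cluster,
                mutated_in=a, unmutated_in=n_in - a,
                mutated_out=c, unmutated_out=n_out - c,
                p_value=float(p),
            ))
    pvals = [r.p_value for r in records]
    adj = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    return [
        EnrichmentResult(
            gene_id=r.gene_id, cluster=r.cluster,
            mutated_in=r.mutated_in, unmutated_in=r.unmutated_in,
            mutated_out=r.mutated_out, unmutated_out=r.unmutated_out,
            p_value=r.p_value, adjusted_p=float(q),
        )
        for r, q in zip(records, adj)
    ]


def _pearson_ward_labels(x: np.ndarray, k: int) -> np.ndarray:
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    unit = centered / norms[:, None]
    d = np.clip(1.0 - unit @ unit.T, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="ward")
    return fcluster(z, t=k, criterion="maxclust")


def classify_emt(
    expr: ExpressionMatrix,
    signature_up: set,
    signature_down: set,
    delta: float = 0.5,
    k: int = 3,
    min_coverage: float = 0.5,
) -> list[EmtCall]:
    """Label cell lines epithelial / mesenchymal / neither from an EMT
    signature.

    Cell lines are hierarchically clustered (Pearson distance, Ward) on
    the standardized expression of the signature genes and the tree cut
    at ``k`` clusters.  Each cluster is labeled mesenchymal when the mean
    z-score of the up-genes exceeds that of the down-genes by more than
    ``delta``, epithelial for the reverse, neither otherwise.
    """
    signature_up = set(signature_up)
    signature_down = set(signature_down)
    sig = signature_up | signature_down
    present = [g for g in expr.gene_ids if g in sig]
    coverage = len(present) / len(sig)
    if coverage < min_coverage:
        missing = sorted(sig - set(present))
        raise ValueError(
            f"only {coverage:.0%} of signature genes present "
            f"(need >= {min_coverage:.0%}); missing e.g. {missing[:10]}"
        )
    sub = expr.values.loc[present]
    sd = sub.std(axis=1).replace(0, 1.0)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)

    labels = _pearson_ward_labels(z.to_numpy().T, k)
    up_present = [g for g in present if g in signature_up]
    down_present = [g for g in present if g in signature_down]
    calls = []
    cluster_label: dict[int, str] = {}
    for c in sorted(set(labels)):
        cols = [s for s, l in zip(expr.sample_ids, labels) if l == c]
        up_mean = z.loc[up_present, cols].to_numpy().mean() if up_present else 0.0
        down_mean = (
            z.loc[down_present, cols].to_numpy().mean() if down_present else 0.0
        )
        if up_mean - down_mean > delta:
            cluster_label[c] = "mesenchymal"
        elif down_mean - up_mean > delta:
            cluster_label[c] = "epithelial"
        else:
            cluster_label[c] = "neither"
    for s, l in zip(expr.sample_ids, labels):
        calls.append(EmtCall(sample_id=s, label=cluster_label[l]))
    return calls


def _fit_bimodal_positive(
    values: np.ndarray, seed: int, n_init: int = 10
) -> tuple[np.ndarray, bool]:
    """Fit a two-component Gaussian mixture; flag samples in the high mode.

    Returns (positive mask, unimodal flag).  The gene is declared
    unimodal — and every sample negative — when a single Gaussian fits
    at least as well by BIC, or when either component attracts fewer
    than two samples.
    """
    v = values.reshape(-1, 1)
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(v)
    gm = GaussianMixture(
        n_components=2, n_init=n_init, random_state=seed,
        init_params="kmeans", max_iter=200,
    ).fit(v)
    if gm1.bic(v) <= gm.bic(v):
        return np.zeros(len(values), dtype=bool), True
    hi = int(np.argmax(gm.means_.ravel()))
    post = gm.predict_proba(v)[:, hi]
    positive = post > 0.5
    n_hi, n_lo = int(positive.sum()), int((~positive).sum())
    if n_hi < 2 or n_lo < 2:
        return np.zeros(len(values), dtype=bool), True
    return positive, False


def call_breast_subtypes(
    expr: ExpressionMatrix,
    esr1: str = "ESR1",
    pgr: str = "PGR",
    erbb2: str = "ERBB2",
    seed: int = 0,
) -> list[SubtypeCall]:
    """Receptor-status subtype calls from bimodal Gaussian-mixture fits.

    A sample is receptor-positive when its posterior for the
    higher-mean mixture component exceeds 0.5.  ERBB2 positivity takes
    precedence (Her2+); triple negatives lack all three; ESR1-positive
    ERBB2-negative samples are ER+Her2-; everything else is "other".
    """
    for g in (esr1, pgr, erbb2):
        if g not in expr.values.index:
            raise KeyError(f"receptor gene {g!r} not in expression matrix")
    if expr.n_samples < 10:
        raise ValueError("need >= 10 samples for mixture fitting")
    positive = {}
    for g in (esr1, pgr, erbb2):
        vals = expr.values.loc[g].to_numpy(dtype=float)
        pos, unimodal = _fit_bimodal_positive(vals, seed)
        if unimodal:
            import warnings
            warnings.warn(f"expression of {g!r} looks unimodal; calling "
                          "all samples negative")
        positive[g] = pos
    calls = []
    for i, s in enumerate(expr.sample_ids):
        if positive[erbb2][i]:
            label = "Her2+"
        elif positive[esr1][i]:
            label = "ER+Her2-"
        elif not positive[pgr][i]:
            label = "TN"
        else:
            label = "other"
        calls.append(SubtypeCall(sample_id=s, label=label))
    return calls
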