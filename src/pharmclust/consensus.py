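"""Subsampled hierarchical consensus clustering.

Used twice in the pipeline: to group selected genes into co-expression
modules (items = genes, features = cell lines) and to group cell lines
into transcriptomic clusters (items = cell lines, features = genes).

Each iteration draws a random subset of the feature axis, computes
pairwise Pearson distance (1 - r) between items over those features,
applies Ward linkage and cuts the tree at every k of interest.  Items are
never subsampled, so the co-clustering frequency (the consensus matrix)
is defined for every pair at every iteration.  The final partition at a
given k is obtained by hierarchically clustering 1 - consensus with
average linkage, the usual consensus-clustering convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import CellLineClustering, ExpressionMatrix, GeneModule

__all__ = ["ConsensusResult", "consensus_cluster", "select_k",
           "modules_from_gene_clusters", "clustering_from_result"]


@dataclass
class ConsensusResult:
    """Consensus matrices and partitions for every k that was explored."""

    item_ids: tuple[str, ...]
    consensus_matrices: dict[int, np.ndarray]
    assignments_per_k: dict[int, np.ndarray]
    seed: int
    n_iterations: int
    subsample_fraction: float
    chosen_k: int | None = None
    weak_structure: bool = False

    def consensus_matrix(self, k: int | None = None) -> np.ndarray:
        if k is None:
            k = self.chosen_k
        if k is None:
            raise ValueError("no k chosen yet; pass k explicitly")
        return self.consensus_matrices[k]

    def assignment(self, k: int | None = None) -> np.ndarray:
        if k is None:
            k = self.chosen_k
        if k is None:
            raise ValueError("no k chosen yet; pass k explicitly")
        return self.assignments_per_k[k]


def _pearson_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows; zero-variance rows get distance 1."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    r = unit @ unit.T
    np.clip(r, -1.0, 1.0, out=r)
    dead = norms == 0
    if dead.any():
        r[dead, :] = 0.0
        r[:, dead] = 0.0
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return d


def _cut_tree(dist: np.ndarray, k: int, method: str) -> np.ndarray:
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method=method)
    return fcluster(z, t=k, criterion="maxclust")


def consensus_cluster(
    data: ExpressionMatrix,
    axis: str,
    k_range,
    n_iterations: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    linkage_method: str = "ward",
) -> ConsensusResult:
    """Run subsampled consensus clustering along one axis of a matrix.

    Parameters
    ----------
    data : ExpressionMatrix
        Genes x samples log-expression.
    axis : {"rows", "genes", "columns", "samples"}
        Which axis holds the items to cluster; the other axis is the
        feature axis that gets subsampled each iteration.
    k_range : iterable of int
        Numbers of clusters to evaluate; each must be <= number of items.
    """
    if axis in ("rows", "genes"):
        x = data.values.to_numpy(dtype=float)
        item_ids = tuple(data.gene_ids)
    elif axis in ("columns", "samples"):
        x = data.values.to_numpy(dtype=float).T
        item_ids = tuple(data.sample_ids)
    else:
        raise ValueError(f"axis must be rows/genes or columns/samples, got {axis!r}")

    n_items, n_features = x.shape
    if n_items < 3:
        raise ValueError(f"need >= 3 items to cluster, got {n_items}")
    if not 0.0 < subsample_fraction <= 1.0:
        raise ValueError(f"subsample_fraction {subsample_fraction} outside (0, 1]")
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 1:
        raise ValueError("k_range must contain positive integers")
    if k_range[-1] > n_items:
        raise ValueError(
            f"k = {k_range[-1]} exceeds the number of items ({n_items})"
        )

    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = item_ids[int(np.argmax(sd == 0))]
        raise ValueError(
            f"item {bad!r} has zero variance; Pearson distance is undefined"
        )

    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_fraction * n_features)))
    counts = {k: np.zeros((n_items, n_items)) for k in k_range}

    for _ in range(n_iterations):
        if m < n_features:
            idx = rng.choice(n_features, size=m, replace=False)
            sub = x[:, idx]
        else:
            sub = x
        dist = _pearson_distance(sub)
        condensed = squareform(dist, checks=False)
        z = linkage(condensed, method=linkage_method)
        for k in k_range:
            labels = fcluster(z, t=k, criterion="maxclust")
            counts[k] += labels[:, None] == labels[None, :]

    consensus = {k: counts[k] / n_iterations for k in k_range}
    assignments = {}
    for k in k_range:
        if k == 1:
            assignments[k] = np.ones(n_items, dtype=int)
        else:
            d = 1.0 - consensus[k]
            np.fill_diagonal(d, 0.0)
            assignments[k] = _cut_tree(d, k, "average")

    return ConsensusResult(
        item_ids=item_ids,
        consensus_matrices=consensus,
        assignments_per_k=assignments,
        seed=seed,
        n_iterations=n_iterations,
        subsample_fraction=subsample_fraction,
    )


def _cdf_area(consensus: np.ndarray) -> float:
    """Exact area under the empirical CDF of off-diagonal consensus entries.

    For values confined to [0, 1] the integral of the CDF equals
    1 - mean, so no histogram binning is needed.
    """
    iu = np.triu_indices(consensus.shape[0], k=1)
    return float(1.0 - consensus[iu].mean())


def _ambiguity(consensus: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> float:
    """Proportion of ambiguously clustered pairs (consensus inside (lo, hi))."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    return float(np.mean((vals > lo) & (vals < hi)))


def select_k(
    result: ConsensusResult,
    k_range=None,
    tol: float = 0.02,
    override: int | None = None,
    criterion: str = "stability",
) -> int:
    """Choose the number of clusters from the consensus matrices.

    criterion="stability" (default): the chosen k is the largest k whose
    consensus matrix remains crisp — proportion of ambiguous pairs
    (entries strictly between 0.1 and 0.9) at most ``tol``.  Splitting a
    genuine cluster produces iteration-dependent partitions and therefore
    intermediate co-clustering frequencies, so crispness ends at the true
    structure.  If no k is crisp the smallest k is returned and the
    result is flagged ``weak_structure``.

    criterion="delta_area": the largest k whose relative increase in area
    under the consensus CDF over the previous k exceeds ``tol``.

    An explicit ``override`` short-circuits either criterion.
    """
    if k_range is None:
        k_range = sorted(result.consensus_matrices)
    else:
        k_range = sorted(set(int(k) for k in k_range))
        if not k_range:
            raise ValueError("empty k_range")
        missing = [k for k in k_range if k not in result.consensus_matrices]
        if missing:
            raise ValueError(f"no consensus computed for k = {missing}")

    if override is not None:
        if override not in result.assignments_per_k:
            raise ValueError(f"override k = {override} was not computed")
        result.chosen_k = int(override)
        return result.chosen_k

    if criterion == "stability":
        crisp = [k for k in k_range
                 if _ambiguity(result.consensus_matrices[k]) <= tol]
        if crisp:
            result.chosen_k = max(crisp)
        else:
            result.chosen_k = k_range[0]
            result.weak_structure = True
    elif criterion == "delta_area":
        areas = [_cdf_area(result.consensus_matrices[k]) for k in k_range]
        gaining = [
            k for k, prev_a, a in zip(k_range[1:], areas[:-1], areas[1:])
            if prev_a > 0 and (a - prev_a) / prev_a > tol
        ]
        if gaining:
            result.chosen_k = max(gaining)
        else:
            result.chosen_k = k_range[0]
            result.weak_structure = True
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return result.chosen_k


def modules_from_gene_clusters(
    result: ConsensusResult, k: int | None = None, dataset_tag: str = ""
) -> list[GeneModule]:
    """Turn a gene-axis consensus partition into disjoint gene modules."""
    labels = result.assignment(k)
    modules = []
    for lab in sorted(set(labels)):
        genes = frozenset(
            g for g, l in zip(result.item_ids, labels) if l == lab
        )
        modules.append(GeneModule(
            module_id=f"M{lab}", gene_ids=genes, dataset_tag=dataset_tag
        ))
    return modules


def clustering_from_result(
    result: ConsensusResult, k: int | None = None
) -> CellLineClustering:
    """Turn a sample-axis consensus partition into a CellLineClustering."""
    labels = result.assignment(k)
    return CellLineClustering(
        sample_ids=tuple(result.item_ids),
        labels=tuple(f"C{l}" for l in labels),
    )
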