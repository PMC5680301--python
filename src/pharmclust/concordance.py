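"""Agreement between two cell-line clusterings of the same panel.

The similarity matrix counts, for every pair of cell lines, in how many
of the two clusterings the pair falls in the same cluster (0, 1 or 2).
The headline accuracy is the fraction of pairs co-clustered in both
among pairs co-clustered in at least one ("jaccard" style); a Rand-style
alternative counts concordant pairs (0 or 2) over all pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .datatypes import CellLineClustering

__all__ = ["SimilarityMatrix", "ClusterMatch", "build_similarity_matrix",
           "concordance_accuracy", "match_clusters", "order_for_heatmap"]


@dataclass(frozen=True)
class SimilarityMatrix:
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # int matrix with entries in {0, 1, 2}

    def __post_init__(self) -> None:
        c = self.counts
        n = len(self.sample_ids)
        if c.shape != (n, n):
            raise ValueError("counts shape does not match sample_ids")
        if not np.array_equal(c, c.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.isin(c, (0, 1, 2)).all():
            raise ValueError("similarity entries must be 0, 1 or 2")

    def as_frame(self) -> pd.DataFrame:
        ids = list(self.sample_ids)
        return pd.DataFrame(self.counts, index=ids, columns=ids)


@dataclass(frozen=True)
class ClusterMatch:
    """Injective best-overlap mapping from clusters of A to clusters of B."""

    mapping: dict  # label in A -> label in B
    unmatched_a: tuple
    unmatched_b: tuple
    overlap: dict  # (label_a, label_b) -> shared sample count

    def __post_init__(self) -> None:
        targets = list(self.mapping.values())
        if len(targets) != len(set(targets)):
            raise ValueError("cluster match must be injective")


def _check_same_samples(a: CellLineClustering, b: CellLineClustering) -> None:
    if set(a.sample_ids) != set(b.sample_ids):
        only_a = set(a.sample_ids) - set(b.sample_ids)
        only_b = set(b.sample_ids) - set(a.sample_ids)
        raise ValueError(
            f"clusterings cover different samples (A-only: {len(only_a)}, "
            f"B-only: {len(only_b)})"
        )


def build_similarity_matrix(
    a: CellLineClustering, b: CellLineClustering
) -> SimilarityMatrix:
    """Count per pair how many of the two clusterings co-cluster it."""
    _check_same_samples(a, b)
    ids = list(a.sample_ids)
    la = np.asarray(a.labels)
    bmap = dict(zip(b.sample_ids, b.labels))
    lb = np.asarray([bmap[s] for s in ids])
    counts = (
        (la[:, None] == la[None, :]).astype(int)
        + (lb[:, None] == lb[None, :]).astype(int)
    )
    return SimilarityMatrix(sample_ids=tuple(ids), counts=counts)


def concordance_accuracy(
    sim: SimilarityMatrix, definition: str = "jaccard"
) -> float:
    """Fraction of cell-line pairs on which the two clusterings agree.

    definition="jaccard": pairs co-clustered in both / pairs co-clustered
    in at least one (0 with a warning if no pair co-clusters anywhere).
    definition="rand": concordant pairs (count 0 or 2) / all pairs — the
    Rand index of the two partitions.
    """
    n = len(sim.sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples")
    iu = np.triu_indices(n, k=1)
    c = sim.counts[iu]
    if definition == "jaccard":
        denom = int((c >= 1).sum())
        if denom == 0:
            warnings.warn("no pair co-clusters in either clustering; accuracy 0")
            return 0.0
        return float((c == 2).sum() / denom)
    if definition == "rand":
        return float(((c == 0) | (c == 2)).sum() / len(c))
    raise ValueError(f"unknown definition {definition!r}")


def _contingency(a: CellLineClustering, b: CellLineClustering):
    la = a.cluster_labels()
    lb = b.cluster_labels()
    bmap = dict(zip(b.sample_ids, b.labels))
    table = np.zeros((len(la), len(lb)), dtype=int)
    ia = {l: i for i, l in enumerate(la)}
    ib = {l: i for i, l in enumerate(lb)}
    for s, l in zip(a.sample_ids, a.labels):
        table[ia[l], ib[bmap[s]]] += 1
    return la, lb, table


def match_clusters(a: CellLineClustering, b: CellLineClustering) -> ClusterMatch:
    """Maximum-overlap injective assignment between the two label sets.

    Solved as a linear assignment on the contingency table; labels left
    over on either side (when cluster counts differ, or when a pairing
    would share zero samples) are reported unmatched.
    """
    _check_same_samples(a, b)
    la, lb, table = _contingency(a, b)
    rows, cols = linear_sum_assignment(-table)
    mapping = {}
    overlap = {}
    for i, j in zip(rows, cols):
        if table[i, j] > 0:
            mapping[la[i]] = lb[j]
            overlap[(la[i], lb[j])] = int(table[i, j])
    unmatched_a = tuple(l for l in la if l not in mapping)
    used_b = set(mapping.values())
    unmatched_b = tuple(l for l in lb if l not in used_b)
    return ClusterMatch(mapping=mapping, unmatched_a=unmatched_a,
                        unmatched_b=unmatched_b, overlap=overlap)


def order_for_heatmap(sim: SimilarityMatrix) -> pd.DataFrame:
    """Reorder the similarity matrix by hierarchical clustering.

    Pearson distance between similarity rows, Ward linkage; the ordered
    matrix is meant to be handed to an external heatmap renderer.
    """
    c = sim.counts.astype(float)
    centered = c - c.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    unit = centered / norms[:, None]
    d = np.clip(1.0 - unit @ unit.T, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="ward")
    order = leaves_list(z)
    ids = [sim.sample_ids[i] for i in order]
    return pd.DataFrame(c[np.ix_(order, order)], index=ids, columns=ids)
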