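"""Drug-sensitivity analysis of a cell-line clustering.

Raw response metrics are first mapped onto a common scale on which
higher values mean a more sensitive cell line: IC50 in micromolar
becomes -log10 of the molar concentration, mean viability becomes
1 - viability, and AUC passes through (flipped when its declared
orientation is high-is-resistant).

The pseudo-F index scores how tightly a partition groups a drug's
responses; cluster-vs-rest Welch t-tests with per-drug BH adjustment
call sensitive (t > 0) and resistant (t < 0) cluster phenotypes, and the
robust set is the intersection of significant calls across two datasets
with matched clusters and consistent sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .concordance import ClusterMatch
from .datatypes import CellLineClustering, DrugResponseTable

__all__ = [
    "SensitivityVector", "PseudoFReport", "AssociationResult",
    "transform_sensitivity", "pseudo_f", "compare_partitions",
    "cluster_drug_association", "robust_associations",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensitivityVector:
    """One drug's responses on the common high-is-sensitive scale."""

    drug_id: str
    sample_ids: tuple[str, ...]
    values: np.ndarray  # NaN where missing
    source_metric: str

    def present(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass(frozen=True)
class PseudoFReport:
    drug_id: str
    partition: str
    pseudo_f: float          # Calinski-Harabasz form (between/(K-1))/(within/(N-K))
    pseudo_f_as_printed: float  # degrees of freedom transposed
    n: int
    k: int
    infinite: bool = False   # within-group variance was exactly 0


@dataclass(frozen=True)
class AssociationResult:
    drug_id: str
    cluster: str
    t_statistic: float
    p_value: float
    adjusted_p: float
    phenotype: str  # "sensitive" | "resistant"
    n_in: int
    n_out: int

    def __post_init__(self) -> None:
        expected = "sensitive" if self.t_statistic > 0 else "resistant"
        if self.phenotype != expected:
            raise ValueError("phenotype must follow the sign of t")


def transform_sensitivity(table: DrugResponseTable) -> list[SensitivityVector]:
    """Map a drug-response table to the common high-is-sensitive scale."""
    arr = table.values.to_numpy(dtype=float)
    if table.metric == "ic50_uM":
        bad = np.argwhere(arr <= 0)
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"nonpositive IC50 for drug {table.drug_ids[r]!r}, sample "
                f"{table.sample_ids[c]!r}: {arr[r, c]}"
            )
        out = -np.log10(arr * 1e-6)  # uM -> molar
    elif table.metric == "mean_viability":
        out = 1.0 - arr
    elif table.metric == "auc":
        out = arr.copy()
        if table.orientation == "high_is_resistant":
            out = 1.0 - out
    else:  # pragma: no cover - guarded by DrugResponseTable validation
        raise ValueError(f"unknown metric {table.metric!r}")
    samples = tuple(table.sample_ids)
    return [
        SensitivityVector(
            drug_id=d, sample_ids=samples, values=out[i],
            source_metric=table.metric,
        )
        for i, d in enumerate(table.drug_ids)
    ]


def pseudo_f(values: SensitivityVector, partition: dict,
             partition_name: str = "clustering") -> PseudoFReport:
    """Pseudo-F (between/within variance ratio) of one drug under a partition.

    Missing responses are dropped listwise; every retained group must be
    non-empty and at least two groups must remain.  The standard
    Calinski-Harabasz form (between/(K-1)) / (within/(N-K)) is the
    headline value; the variant with transposed degrees of freedom is
    reported alongside.
    """
    mask = values.present()
    labels = np.asarray([partition.get(s) for s in values.sample_ids], dtype=object)
    keep = mask & np.array([l is not None for l in labels])
    x = values.values[keep]
    g = labels[keep]
    groups = pd.unique(g)
    if len(groups) < 2:
        raise ValueError(
            f"drug {values.drug_id!r}: need >= 2 groups with data, got {len(groups)}"
        )
    n, k = len(x), len(groups)
    grand = x.mean()
    between = 0.0
    within = 0.0
    for lab in groups:
        xi = x[g == lab]
        m = xi.mean()
        between += len(xi) * (m - grand) ** 2
        within += ((xi - m) ** 2).sum()
    if within == 0.0 and between == 0.0:
        # all retained responses identical: no separation at all
        return PseudoFReport(
            drug_id=values.drug_id, partition=partition_name,
            pseudo_f=0.0, pseudo_f_as_printed=0.0, n=n, k=k,
        )
    if within == 0.0:
        return PseudoFReport(
            drug_id=values.drug_id, partition=partition_name,
            pseudo_f=np.inf, pseudo_f_as_printed=np.inf,
            n=n, k=k, infinite=True,
        )
    standard = (between / (k - 1)) / (within / (n - k))
    as_printed = (between / (n - k)) / (within / (k - 1))
    return PseudoFReport(
        drug_id=values.drug_id, partition=partition_name,
        pseudo_f=float(standard), pseudo_f_as_printed=float(as_printed),
        n=n, k=k,
    )


def compare_partitions(
    vectors: list[SensitivityVector],
    clustering: CellLineClustering,
    tissue_labels: dict,
) -> pd.DataFrame:
    """Per drug, pseudo-F under the transcriptomic clustering vs tissue.

    Returns a table with one row per drug plus a paired two-sided t-test
    on the per-drug pseudo-F pairs (NaN when fewer than two drugs).
    """
    if not vectors:
        raise ValueError("no drugs to compare")
    cl = dict(zip(clustering.sample_ids, clustering.labels))
    rows = []
    for v in vectors:
        f_cl = pseudo_f(v, cl, "clustering")
        f_ti = pseudo_f(v, tissue_labels, "tissue")
        rows.append({
            "drug_id": v.drug_id,
            "pseudo_f_clustering": f_cl.pseudo_f,
            "pseudo_f_tissue": f_ti.pseudo_f,
            "clustering_wins": f_cl.pseudo_f > f_ti.pseudo_f,
        })
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        t, p = stats.ttest_rel(df["pseudo_f_clustering"], df["pseudo_f_tissue"])
    else:
        t, p = np.nan, np.nan
    df.attrs["paired_t"] = float(t)
    df.attrs["paired_p"] = float(p)
    df.attrs["n_clustering_wins"] = int(df["clustering_wins"].sum())
    return df


def cluster_drug_association(
    vectors: list[SensitivityVector],
    clustering: CellLineClustering,
    fdr_alpha: float = 0.05,
    min_group: int = 3,
    fdr_family: str = "per_drug",
) -> list[AssociationResult]:
    """Welch t-tests of each cluster vs the rest for every drug.

    BH adjustment is applied within each drug across its cluster tests
    (``fdr_family="per_drug"``) or across all (drug, cluster) pairs
    (``"global"``).  Undersized groups (fewer than ``min_group``
    non-missing values on either side) are skipped with a log entry.
    """
    if fdr_family not in ("per_drug", "global"):
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    members = {c: set(clustering.members(c)) for c in clustering.cluster_labels()}
    raw: list[tuple[str, str, float, float, int, int]] = []
    for v in vectors:
        present = v.present()
        vals = v.values
        for cluster, mem in members.items():
            in_mask = np.array([s in mem for s in v.sample_ids]) & present
            out_mask = ~np.array([s in mem for s in v.sample_ids]) & present
            n_in, n_out = int(in_mask.sum()), int(out_mask.sum())
            if n_in < min_group or n_out < min_group:
                logger.info(
                    "skipping drug %s cluster %s: %d in / %d out non-missing",
                    v.drug_id, cluster, n_in, n_out,
                )
                continue
            t, p = stats.ttest_ind(vals[in_mask], vals[out_mask], equal_var=False)
            if np.isnan(t):
                continue
            raw.append((v.drug_id, cluster, float(t), float(p), n_in, n_out))

    results: list[AssociationResult] = []
    if not raw:
        return results
    if fdr_family == "global":
        adj = multipletests([r[3] for r in raw], method="fdr_bh")[1]
        adj_map = dict(zip(range(len(raw)), adj))
    else:
        adj_map = {}
        by_drug: dict[str, list[int]] = {}
        for i, r in enumerate(raw):
            by_drug.setdefault(r[0], []).append(i)
        for idxs in by_drug.values():
            adj = multipletests([raw[i][3] for i in idxs], method="fdr_bh")[1]
            for i, q in zip(idxs, adj):
                adj_map[i] = q
    for i, (drug, cluster, t, p, n_in, n_out) in enumerate(raw):
        results.append(AssociationResult(
            drug_id=drug, cluster=cluster, t_statistic=t, p_value=p,
            adjusted_p=float(adj_map[i]),
            phenotype="sensitive" if t > 0 else "resistant",
            n_in=n_in, n_out=n_out,
        ))
    return results


def significant(results: list[AssociationResult],
                fdr_alpha: float = 0.05) -> list[AssociationResult]:
    return [r for r in results if r.adjusted_p < fdr_alpha]


def robust_associations(
    a: list[AssociationResult],
    b: list[AssociationResult],
    match: ClusterMatch,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Significant calls shared by two datasets with consistent phenotype.

    Clusters of A are translated to B via ``match``; records whose
    cluster has no counterpart are excluded and counted in the returned
    table's ``attrs["n_unmatched"]``.
    """
    sig_a = significant(a, fdr_alpha)
    sig_b = {(r.drug_id, r.cluster): r for r in significant(b, fdr_alpha)}
    rows = []
    n_unmatched = 0
    for r in sig_a:
        if r.cluster not in match.mapping:
            n_unmatched += 1
            continue
        key = (r.drug_id, match.mapping[r.cluster])
        other = sig_b.get(key)
        if other is not None and other.phenotype == r.phenotype:
            rows.append({
                "drug_id": r.drug_id,
                "cluster_a": r.cluster,
                "cluster_b": other.cluster,
                "phenotype": r.phenotype,
                "t_a": r.t_statistic,
                "t_b": other.t_statistic,
                "adjusted_p_a": r.adjusted_p,
                "adjusted_p_b": other.adjusted_p,
            })
    df = pd.DataFrame(
        rows, columns=["drug_id", "cluster_a", "cluster_b", "phenotype",
                       "t_a", "t_b", "adjusted_p_a", "adjusted_p_b"],
    )
    df.attrs["n_unmatched"] = n_unmatched
    return df
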