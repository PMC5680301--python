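"""Core domain types shared by every pipeline stage.

All tabular containers wrap a :class:`pandas.DataFrame` with genes (or
drugs) in rows and cell lines in columns, mirroring the layout of the
expression and drug-screen exports the pipeline consumes.  Validation
happens at construction time so downstream stages can assume clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "DrugResponseTable",
    "MutationMatrix",
    "InteractionGraph",
    "CellLineClustering",
    "GeneModule",
    "AnalysisConfig",
]


class ValidationError(ValueError):
    """An input table violated one of the documented invariants."""


def _check_unique(ids: Sequence[str], kind: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 gene-expression values, genes in rows, cell lines in columns.

    Values must be finite everywhere: expression matrices are assumed
    complete (missingness is a property of drug-response data only).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[list(samples)])


Metric = Literal["ic50_uM", "auc", "mean_viability"]
Orientation = Literal["high_is_sensitive", "high_is_resistant"]


@dataclass(frozen=True)
class DrugResponseTable:
    """Drug-sensitivity measurements, drugs in rows, cell lines in columns.

    ``metric`` declares the assay readout; ``orientation`` says whether
    large raw values mean a sensitive cell line.  Missing measurements are
    NaN — never zero.
    """

    values: pd.DataFrame
    metric: Metric
    orientation: Orientation

    _METRICS = ("ic50_uM", "auc", "mean_viability")
    _ORIENTATIONS = ("high_is_sensitive", "high_is_resistant")

    def __post_init__(self) -> None:
        if self.metric not in self._METRICS:
            raise ValidationError(f"unknown metric {self.metric!r}")
        if self.orientation not in self._ORIENTATIONS:
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        _check_unique(self.values.index, "drug")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("drug-response values must be numeric")
        if np.isinf(arr).any():
            raise ValidationError("infinite drug-response value")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class MutationMatrix:
    """Binary somatic-mutation calls, genes in rows, cell lines in columns."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("mutation matrix entries must be 0 or 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class InteractionGraph:
    """Undirected scored gene–gene interactions (combined scores in [0,1]).

    Stored as a mapping from unordered gene pairs to scores; at most one
    edge per pair, no self-loops.
    """

    edges: dict[frozenset, float]

    @classmethod
    def from_edge_list(
        cls, triples: Sequence[tuple[str, str, float]]
    ) -> "InteractionGraph":
        edges: dict[frozenset, float] = {}
        for a, b, s in triples:
            a, b = str(a), str(b)
            if a == b:
                raise ValidationError(f"self-loop on gene {a!r}")
            s = float(s)
            if not 0.0 <= s <= 1.0:
                raise ValidationError(
                    f"edge score {s} for ({a}, {b}) outside [0, 1]"
                )
            key = frozenset((a, b))
            if key in edges:
                raise ValidationError(f"duplicate edge between {a!r} and {b!r}")
            edges[key] = s
        return cls(edges)

    def neighbors(self, gene: str, score_min: float = 0.0) -> dict[str, float]:
        out: dict[str, float] = {}
        for pair, score in self.edges.items():
            if gene in pair and score >= score_min:
                (other,) = pair - {gene}
                out[other] = score
        return out

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class CellLineClustering:
    """A hard partition of cell lines into clusters."""

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")
        if len(self.sample_ids) != len(self.labels):
            raise ValidationError("labels and sample_ids differ in length")

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "CellLineClustering":
        items = list(mapping.items())
        return cls(
            sample_ids=tuple(s for s, _ in items),
            labels=tuple(str(l) for _, l in items),
        )

    @property
    def k(self) -> int:
        return len(set(self.labels))

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=list(self.sample_ids), name="cluster")

    def members(self, label: str) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == label]

    def cluster_labels(self) -> list[str]:
        seen: list[str] = []
        for l in self.labels:
            if l not in seen:
                seen.append(l)
        return seen


@dataclass(frozen=True)
class GeneModule:
    """A named, non-empty set of genes found to co-vary in one dataset."""

    module_id: str
    gene_ids: frozenset
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError(f"module {self.module_id!r} is empty")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the full pipeline with study defaults.

    By default, interaction edges are kept at combined score >= 0.7,
    co-expression at Pearson r >= 0.5, and associations are called at
    BH-adjusted p < 0.05.  Consensus clustering resamples 1000 times.
    """

    edge_score_min: float = 0.7
    correlation_min: float = 0.5
    fdr_alpha: float = 0.05
    n_iterations: int = 1000
    subsample_fraction: float = 0.8
    distance: str = "pearson"
    linkage: str = "ward"
    gene_k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    sample_k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12)
    gene_k: int | None = None  # explicit override; None = delta-area criterion
    sample_k: int | None = None
    delta_area_tol: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_score_min", "correlation_min", "fdr_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValidationError(
                f"subsample_fraction = {self.subsample_fraction} outside (0, 1]"
            )
        for name in ("gene_k_range", "sample_k_range"):
            ks = getattr(self, name)
            if not ks or any(k < 1 for k in ks):
                raise ValidationError(f"{name} must be non-empty positive ints")

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)
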