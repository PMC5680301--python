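"""Reading and writing the tab-separated formats the pipeline exchanges.

Dialect: UTF-8, tab-separated, "." decimal.  Expression and mutation
matrices must be complete; drug-response tables encode missing entries as
empty fields.  Gene signatures use the GMT convention (set name,
description, then member genes, one set per line).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CellLineClustering,
    DrugResponseTable,
    ExpressionMatrix,
    InteractionGraph,
    MutationMatrix,
    ValidationError,
)

__all__ = [
    "load_expression_matrix",
    "save_expression_matrix",
    "load_drug_response",
    "save_drug_response",
    "load_mutation_matrix",
    "save_mutation_matrix",
    "load_interaction_graph",
    "save_interaction_graph",
    "load_clustering",
    "save_clustering",
    "read_gmt",
    "write_gmt",
    "harmonize_datasets",
    "file_checksum",
]

_SEP = "\t"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_SEP, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def _to_numeric_strict(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Parse every cell as a float; report coordinates of the first failure."""
    out = np.empty(df.shape, dtype=float)
    arr = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = arr[i, j]
            try:
                out[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric {what} value {cell!r} at row "
                    f"{df.index[i]!r}, column {df.columns[j]!r}"
                ) from None
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def load_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Load a complete genes x samples log-expression TSV."""
    df = _read_table(path)
    return ExpressionMatrix(_to_numeric_strict(df, "expression"))


def save_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep=_SEP, index_label="gene_id")


def load_drug_response(
    path: str | Path, metric: str, orientation: str
) -> DrugResponseTable:
    """Load a drugs x samples response TSV; empty fields become NaN."""
    df = _read_table(path)
    num = np.empty(df.shape, dtype=float)
    arr = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = arr[i, j].strip() if isinstance(arr[i, j], str) else arr[i, j]
            if cell == "":
                num[i, j] = np.nan
            else:
                try:
                    num[i, j] = float(cell)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric response value {cell!r} at drug "
                        f"{df.index[i]!r}, sample {df.columns[j]!r}"
                    ) from None
    values = pd.DataFrame(num, index=df.index, columns=df.columns)
    return DrugResponseTable(values=values, metric=metric, orientation=orientation)


def save_drug_response(table: DrugResponseTable, path: str | Path) -> None:
    table.values.to_csv(path, sep=_SEP, index_label="drug_id", na_rep="")


def load_mutation_matrix(path: str | Path) -> MutationMatrix:
    df = _to_numeric_strict(_read_table(path), "mutation")
    return MutationMatrix(df.astype(int))


def save_mutation_matrix(mut: MutationMatrix, path: str | Path) -> None:
    mut.values.to_csv(path, sep=_SEP, index_label="gene_id")


def load_interaction_graph(path: str | Path) -> InteractionGraph:
    """Load a 3-column (gene_a, gene_b, score) edge-list TSV with header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_SEP, dtype={0: str, 1: str})
    if df.shape[1] != 3:
        raise ValidationError(
            f"interaction graph file must have 3 columns, found {df.shape[1]}"
        )
    triples = [
        (str(a), str(b), float(s)) for a, b, s in df.itertuples(index=False)
    ]
    return InteractionGraph.from_edge_list(triples)


def save_interaction_graph(graph: InteractionGraph, path: str | Path) -> None:
    rows = []
    for pair, score in graph.edges.items():
        a, b = sorted(pair)
        rows.append((a, b, score))
    rows.sort()
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(
        path, sep=_SEP, index=False
    )


def load_clustering(path: str | Path) -> CellLineClustering:
    """Load a two-column (sample_id, cluster) assignment TSV."""
    df = pd.read_csv(Path(path), sep=_SEP, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("clustering file needs sample_id and cluster columns")
    return CellLineClustering(
        sample_ids=tuple(df.iloc[:, 0]), labels=tuple(df.iloc[:, 1])
    )


def save_clustering(clustering: CellLineClustering, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": clustering.sample_ids, "cluster": clustering.labels}
    ).to_csv(path, sep=_SEP, index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file: name, description, member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"malformed GMT line: {line[:60]!r}")
        name = fields[0]
        if name in sets:
            raise ValidationError(f"duplicate gene set {name!r} in GMT")
        sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *map(str, genes)]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def harmonize_datasets(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two expression matrices to their shared genes and samples.

    Output row/column orders are identical (gene and sample order taken
    from ``a``), so downstream per-position comparisons line up.
    Identifiers are matched exactly and case-sensitively.
    """
    genes = [g for g in a.gene_ids if g in set(b.gene_ids)]
    samples = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if not genes:
        raise ValidationError("no genes shared between the two datasets")
    if not samples:
        raise ValidationError("no samples shared between the two datasets")
    a2 = ExpressionMatrix(a.values.loc[genes, samples])
    b2 = ExpressionMatrix(b.values.loc[genes, samples])
    return a2, b2


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
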