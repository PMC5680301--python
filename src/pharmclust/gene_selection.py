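"""Variant-gene selection by the IQR inflexion-point (knee) method.

Per-gene interquartile ranges are sorted ascending; the knee of the sorted
curve is the point furthest from the chord joining its endpoints, after
rescaling both axes to [0, 1] so the answer does not depend on units.
Genes with IQR strictly above the knee value are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix

__all__ = ["IqrProfile", "InflexionResult", "compute_iqr_profile",
           "find_inflexion_point", "select_variant_genes"]


@dataclass(frozen=True)
class IqrProfile:
    """Per-gene IQRs sorted ascending (ties broken by gene ID)."""

    gene_ids: tuple[str, ...]
    iqr_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.iqr_values):
            raise ValueError("gene_ids and iqr_values differ in length")
        vals = np.asarray(self.iqr_values)
        if len(vals) and np.any(np.diff(vals) < 0):
            raise ValueError("iqr_values must be sorted ascending")


@dataclass(frozen=True)
class InflexionResult:
    knee_index: int
    threshold: float
    selected_gene_ids: frozenset


def compute_iqr_profile(expr: ExpressionMatrix) -> IqrProfile:
    """Compute each gene's IQR (Q3 - Q1, linear-interpolation quantiles).

    Requires at least 4 samples so that quartiles are meaningful.
    """
    if expr.n_samples < 4:
        raise ValueError(
            f"IQR profile needs >= 4 samples, got {expr.n_samples}"
        )
    arr = expr.values.to_numpy()
    q1, q3 = np.percentile(arr, [25, 75], axis=1)
    iqr = q3 - q1
    order = sorted(range(len(iqr)), key=lambda i: (iqr[i], expr.gene_ids[i]))
    return IqrProfile(
        gene_ids=tuple(expr.gene_ids[i] for i in order),
        iqr_values=tuple(float(iqr[i]) for i in order),
    )


def _chord_distances(y: np.ndarray) -> np.ndarray:
    """Distance of each point of the sorted curve to its endpoint chord.

    Both axes are rescaled to [0, 1] first; collinear points get 0.
    """
    n = len(y)
    x = np.arange(n, dtype=float) / (n - 1)
    span = y[-1] - y[0]
    ys = (y - y[0]) / span
    # chord runs from (0, 0) to (1, 1); |cross product| / chord length
    return np.abs(x * ys[-1] - ys * x[-1]) / np.sqrt(2.0)


def find_inflexion_point(profile: IqrProfile) -> InflexionResult:
    """Locate the knee of the ascending IQR curve.

    The knee maximises the perpendicular distance to the chord between the
    first and last points; ties go to the larger index so that fewer genes
    pass the resulting threshold.  Selected genes are those with IQR
    strictly greater than the knee's IQR.
    """
    y = np.asarray(profile.iqr_values, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 IQR values to locate a knee")
    if y[-1] == y[0]:
        raise ValueError(
            "all IQR values are equal; the chord is degenerate — consider "
            "selecting a fixed fraction of genes instead"
        )
    d = _chord_distances(y)
    knee = int(len(d) - 1 - np.argmax(d[::-1]))  # ties -> larger index
    threshold = float(y[knee])
    selected = frozenset(
        g for g, v in zip(profile.gene_ids, profile.iqr_values) if v > threshold
    )
    return InflexionResult(knee_index=knee, threshold=threshold,
                           selected_gene_ids=selected)


def select_variant_genes(expr: ExpressionMatrix) -> frozenset:
    """IQR profile + knee detection in one call; returns the gene-ID set."""
    return find_inflexion_point(compute_iqr_profile(expr)).selected_gene_ids
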