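import numpy as np
import pandas as pd
import pytest

from pharmclust import (
    AnalysisConfig,
    ExpressionMatrix,
    GeneratorConfig,
    generate_bundle,
    run_study,
)


def expr_from_array(arr, genes=None, samples=None) -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


@pytest.fixture(scope="session")
def default_bundle():
    """The paired synthetic study at its default scale (shared run)."""
    return generate_bundle(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_study(default_bundle):
    """Full pipeline on the default bundle with the 100-iteration profile."""
    b = default_bundle
    truth = b["truth"]
    config = AnalysisConfig(n_iterations=100, seed=7)
    return run_study(
        b["expression_a"], b["expression_b"], b["graph"], config,
        drugs_a=b["drugs_a"], drugs_b=b["drugs_b"],
        mutations=b["mutations"], tissues=truth.tissue_labels,
        gsea_permutations=200,
    )


@pytest.fixture
def small_expr():
    rng = np.random.default_rng(0)
    return expr_from_array(rng.normal(5, 1, size=(10, 8)))
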