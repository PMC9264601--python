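import numpy as np
import pandas as pd
import pytest

from exhaustclass import simulate
from exhaustclass.eic import ClassLabels
from exhaustclass.io import ExpressionMatrix, GeneSet, GeneSetCollection


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale cohort (2000 genes x 200 samples, planted k=4)."""
    em, truth = simulate.simulate_expression(seed=42)
    return em, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for unit tests that only need the planted structure."""
    em, truth = simulate.simulate_expression(n_genes=600, n_samples=120, seed=7)
    return em, truth


@pytest.fixture(scope="session")
def signature_collection(small_cohort):
    _, truth = small_cohort
    return GeneSetCollection(
        [GeneSet(name, f"planted {name}", frozenset(members))
         for name, members in truth.planted_signature_genes.items()]
    )


@pytest.fixture()
def planted_labels(small_cohort):
    _, truth = small_cohort
    return ClassLabels(truth.planted_class.copy())


@pytest.fixture()
def tiny_expression():
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(4, 3) + 1.0,
        index=["G1", "G2", "G3", "G4"],
        columns=["S1", "S2", "S3"],
    )
    return ExpressionMatrix(values, "log2")
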