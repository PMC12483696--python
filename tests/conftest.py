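import numpy as np
import pytest

from polycdm import AttributeSpec, QMatrix, SimulationDesign
from polycdm.estimation import FitOptions, ModelConfig, fit_em


@pytest.fixture(scope="session")
def spec333() -> AttributeSpec:
    return AttributeSpec((3, 3, 3))


@pytest.fixture(scope="session")
def small_dataset():
    """A small but informative dataset with a known generating model.

    Two 3-level attributes, 8 items, N=600, high-quality saturated truth.
    Returned as (design, qmatrix, true_models, patterns, responses).
    """
    design = SimulationDesign(
        K=2, levels=(3, 3), J=8, N=600, quality="high", replications=1, seed=42
    )
    spec = design.spec
    entries = np.array(
        [[1, 0], [2, 0], [0, 1], [0, 2], [1, 1], [2, 2], [1, 2], [2, 1]]
    )
    Q = QMatrix(entries, spec)
    models = design.true_item_models(Q)
    patterns, X = design.replicate(0, Q, models)
    return design, Q, models, patterns, X


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    _, Q, _, _, X = small_dataset
    return fit_em(X, Q, ModelConfig(), FitOptions(seed=3))
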