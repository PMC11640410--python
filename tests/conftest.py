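import numpy as np
import pandas as pd
import pytest

from mirmeta.studies import ExpressionStudy


def two_group_study(
    rng: np.random.Generator,
    n_features: int = 10,
    n1: int = 5,
    n2: int = 5,
    effects=None,
    sigma: float = 0.5,
    feature_prefix: str = "hsa-miR-",
    study_id: str = "study",
) -> ExpressionStudy:
    """Small complete two-group study with optional per-feature group shifts."""
    base = rng.normal(7.0, 1.0, size=n_features)
    mat = base[:, None] + rng.normal(0.0, sigma, size=(n_features, n1 + n2))
    if effects is not None:
        mat[:, :n1] += np.asarray(effects, dtype=float)[:, None]
    features = [f"{feature_prefix}{i + 1}-5p" for i in range(n_features)]
    samples = [f"{study_id}_R{j}" for j in range(n1)] + [
        f"{study_id}_C{j}" for j in range(n2)
    ]
    groups = pd.Series(["resistant"] * n1 + ["control"] * n2, index=samples)
    return ExpressionStudy(
        values=pd.DataFrame(mat, index=features, columns=samples),
        groups=groups,
        study_id=study_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
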