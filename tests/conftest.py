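import numpy as np
import pandas as pd
import pytest

from ardi.simulate import generate_dataset


def make_panel(scores: dict[tuple[str, str, str], float]) -> pd.DataFrame:
    """Build a long-format score panel from {(voc, feature, rater): score}."""
    rows = [
        {"vocalization_id": v, "feature": f, "rater_id": r, "score": s}
        for (v, f, r), s in scores.items()
    ]
    return pd.DataFrame(rows)


def single_feature_panel(feature: str, by_rater: dict[str, list[float]]) -> pd.DataFrame:
    """Panel for one feature: rater -> scores over vocalizations v1, v2, ..."""
    scores = {}
    for rater, vals in by_rater.items():
        for i, s in enumerate(vals):
            scores[(f"v{i + 1}", feature, rater)] = float(s)
    return make_panel(scores)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across tests (seed 1)."""
    return generate_dataset(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
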