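from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shortform import generate, make_preset, split, subscale_scores, sum_scores
from shortform.targets import TargetScores

STICSA_ASSIGNMENT = {
    f"item_{i + 1:02d}": ("cognitive" if i < 11 else "somatic") for i in range(22)
}


@pytest.fixture(scope="session")
def sticsa_spec():
    return make_preset("sticsa_like")


@pytest.fixture(scope="session")
def sticsa_data(sticsa_spec):
    """One fixed 2000-respondent draw from the two-factor preset."""
    return generate(sticsa_spec, seed=7, n=2000)


@pytest.fixture(scope="session")
def sticsa_splits(sticsa_data):
    """(train, validation, test) response/sum-target pairs."""
    y = sum_scores(sticsa_data.responses)
    parts = split(len(sticsa_data.responses), (0.6, 0.15, 0.25), seed=7)
    out = []
    for idx in (parts.train_idx, parts.validation_idx, parts.test_idx):
        out.append(
            (
                sticsa_data.responses.iloc[idx].reset_index(drop=True),
                TargetScores(y.values.iloc[idx].reset_index(drop=True), kind="sum"),
            )
        )
    return tuple(out)


@pytest.fixture
def toy_responses():
    """Six items, 40 respondents, integer codes 1-4; seeded."""
    rng = np.random.default_rng(42)
    data = rng.integers(1, 5, size=(40, 6))
    return pd.DataFrame(data, columns=[f"item_{i + 1:02d}" for i in range(6)])


def toy_targets(responses: pd.DataFrame, kind: str = "sum") -> TargetScores:
    return sum_scores(responses) if kind == "sum" else subscale_scores(
        responses, STICSA_ASSIGNMENT
    )
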