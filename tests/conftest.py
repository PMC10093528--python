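import numpy as np
import pytest

from fnnsweep import SyntheticConfig, generate_dataset
from fnnsweep.evaluation import CVResult
from fnnsweep.fnn import HyperParams


@pytest.fixture(scope="session")
def small_dataset():
    """Small signal-bearing cohort shared by training-level tests."""
    return generate_dataset(SyntheticConfig(n_cases=200, seed=42, effect_scale=1.0))


@pytest.fixture(scope="session")
def noise_dataset():
    """Pure-noise cohort: labels independent of every feature."""
    return generate_dataset(SyntheticConfig(n_cases=200, seed=7, effect_scale=0.0,
                                            interaction_pairs=0))


@pytest.fixture
def fast_hp():
    """Cheap setting for tests that must actually train networks."""
    return HyperParams(epochs=3, batch_size=64, hidden_width=8,
                       n_hidden_layers=1, dropout_rate=0.0, decay=0.0)


def constant_cv_result(train_auc=0.9, test_auc=0.8):
    return CVResult([train_auc] * 5, [test_auc] * 5)


def brute_force_auc(labels, scores):
    """All-pairs Mann-Whitney oracle: O(n_pos * n_neg), ties count 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
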