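import numpy as np
import pytest

import paireval as pe


@pytest.fixture
def toy():
    """Fixed 8-sample binary dataset with hand-enumerated AUC 11/16."""
    samples, scores, expected = pe.make_toy_fixture()
    return samples, scores, expected


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_instance(rng, n=None, n_classes=None, tie_scores=False):
    """A random ordinal (label, score) instance for oracle comparisons."""
    if n is None:
        n = int(rng.integers(2, 60))
    if n_classes is None:
        n_classes = int(rng.integers(2, 6))
    labels = rng.integers(0, n_classes, n).astype(float)
    scores = rng.standard_normal(n)
    if tie_scores:
        scores = np.round(scores, 1)
    samples = [
        pe.LabeledSample(sample_id=f"s{i:04d}", label=float(labels[i]))
        for i in range(n)
    ]
    table = pe.ScoreTable(
        entries={f"s{i:04d}": float(scores[i]) for i in range(n)}
    )
    return samples, table
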