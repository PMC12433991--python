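import numpy as np
import pytest

from rapep import (
    MotifSearchParams,
    SyntheticSpec,
    build_feature_matrix,
    discover_motifs,
    generate_dataset,
    get_scheme,
    train_cv,
)
from rapep.datasets import AMINO_ACIDS


def random_peptides(rng: np.random.Generator, n: int, lo: int = 9, hi: int = 20) -> list[str]:
    """Uniform random peptides with lengths in [lo, hi]."""
    return [
        "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(lo, hi + 1)))
        for _ in range(n)
    ]


class StubBundle:
    """Duck-typed model bundle returning a fixed per-sequence score,
    used to test score-combination logic in isolation."""

    families = ["AAC"]
    family_params = {}
    threshold = 0.5

    def __init__(self, scores):
        self.scores = dict(scores)

    def predict_proba(self, m):
        return np.array([self.scores[i] for i in m.index])


@pytest.fixture(scope="session")
def betts():
    return get_scheme("betts_russell")


@pytest.fixture(scope="session")
def tiny_data():
    """Small labelled synthetic dataset shared across model tests."""
    return generate_dataset(SyntheticSpec(n_pos=30, n_neg=30, seed=5))


@pytest.fixture(scope="session")
def lr_bundle(tiny_data):
    """A quickly trained logistic-regression bundle on AAC features."""
    m = build_feature_matrix(tiny_data, families=("AAC",))
    bundle, report = train_cv(m, tiny_data.labels, algorithm="LR",
                              grid={"clf__C": [1.0]}, seed=0)
    return bundle, report


@pytest.fixture(scope="session")
def tiny_motifs(tiny_data, betts):
    return discover_motifs(
        tiny_data.positives, tiny_data.negatives, betts,
        MotifSearchParams(fp=2, fn=0, k=5, max_len=4),
    )
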