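import numpy as np
import pytest

from mifex import LabeledMatrixSet, SyntheticConfig, generate_dataset


def random_matrix_set(
    seed: int, n_classes: int = 2, n_per_class: int = 5, n_f: int = 3, n_g: int = 4,
    mean_scale: float = 1.0,
) -> LabeledMatrixSet:
    """Small random labeled set with distinct class means."""
    rng = np.random.default_rng(seed)
    mats, labels = [], []
    for c in range(1, n_classes + 1):
        M = mean_scale * rng.standard_normal((n_f, n_g))
        for _ in range(n_per_class):
            mats.append(M + 0.5 * rng.standard_normal((n_f, n_g)))
            labels.append(c)
    return LabeledMatrixSet(
        matrices=np.array(mats), labels=np.array(labels, dtype=np.int64)
    )


@pytest.fixture
def small_set():
    return random_matrix_set(seed=0)


@pytest.fixture(scope="session")
def benchmark_epochs():
    """The default two-class ERD benchmark dataset (fixed seed)."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_epochs():
    """A lighter ERD dataset for pipeline plumbing tests."""
    return generate_dataset(
        SyntheticConfig(trials_per_class=20, trial_len_s=2.0, seed=1)
    )
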