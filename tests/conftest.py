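import numpy as np
import pytest

from pdglove import ContingencyTable

# The three system-vs-clinician contingency tables from the glove study
# (rows = system grades, columns = clinician grades).  The flexibility
# and strength tables cover the 12 subjects; the stability table is the
# classifier's test-set confusion matrix (n = 24) read as a rater table.

FLEXIBILITY_TABLE = ContingencyTable(
    labels=["F2", "F3", "F4"],
    counts=[[2, 0, 0],
            [1, 1, 0],
            [0, 0, 8]],
)

STRENGTH_TABLE = ContingencyTable(
    labels=["M0", "M2", "M4", "M5"],
    counts=[[1, 0, 0, 0],
            [0, 3, 0, 0],
            [0, 0, 6, 0],
            [0, 0, 1, 1]],
)

STABILITY_CONFUSION = np.array(
    [[8, 0, 0],
     [0, 9, 1],
     [0, 0, 6]]
)

STABILITY_TABLE = ContingencyTable(
    labels=["No tremor", "Mild tremor", "Severe tremor"],
    counts=STABILITY_CONFUSION,
)


@pytest.fixture(scope="session")
def tremor_dataset():
    """A small balanced feature table for classifier tests."""
    from pdglove import simulate_dataset

    features, labels = simulate_dataset(45, (15, 15, 15), seed=7)
    return features.to_numpy(), labels


@pytest.fixture(scope="session")
def separable_features():
    """Linearly separable 3-class features in 9 dimensions."""
    rng = np.random.default_rng(11)
    centers = np.zeros((3, 9))
    centers[0, 0], centers[1, 1], centers[2, 2] = 8.0, 8.0, 8.0
    X = np.vstack([rng.normal(c, 0.5, size=(20, 9)) for c in centers])
    y = np.repeat([0, 1, 2], 20)
    return X, y
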