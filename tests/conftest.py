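import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from lrcomm import stack, synthgen


@pytest.fixture(scope="session")
def separable_data():
    """Two-cluster separable pair features (separation 4 sd, n=400 labelled).

    Positives come from the origin cluster, negatives from the displaced
    true-negative half of the unlabeled pool; a stratified quarter is held
    out for evaluation.
    """
    spec = synthgen.SynthSpec(
        seed=11, n_pos=200, n_unlabeled=400, feature_dim=64, separation=4.0
    )
    pos, unl, truth = synthgen.gen_pair_classification(spec)
    X_neg = np.array([u.x for u in unl])[truth == 1][:200]
    X = np.vstack([np.array([p.x for p in pos]), X_neg])
    y = np.array([1] * 200 + [0] * 200)
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=0.25, stratify=y, random_state=7
    )
    return {
        "X": X,
        "y": y,
        "X_train": X_train,
        "y_train": y_train,
        "X_test": X_test,
        "y_test": y_test,
    }


@pytest.fixture(scope="session")
def stacked_model(separable_data):
    """One stacking ensemble trained on the separable fixture, reused across
    tests (training the CNN/MHA is the expensive step)."""
    return stack.fit_stacking(
        separable_data["X_train"], separable_data["y_train"], seed=5
    )
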