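"""Shared fixtures and mock components.

Mock learners (positive-rate, memorizing, coin-flip, constant) plug into
the learner registry so that stacking internals can be checked against
brute-force oracles; a content-hash "noise" encoder provides a feature
block that is deterministic per sequence yet carries no label signal.
"""

import hashlib

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from sixmastack.encoders import EncoderSpec, register_encoder
from sixmastack.stacking import BaseLearnerSpec, register_learner
from sixmastack.synthetic import generate_dataset, make_pwm


class PositiveRateLearner(BaseEstimator, ClassifierMixin):
    """Predicts, for every sample, the positive rate of its training rows."""

    def fit(self, X, y):
        y = np.asarray(y)
        self.rate_ = float(np.mean(y))
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        n = np.asarray(X).shape[0]
        return np.column_stack([np.full(n, 1 - self.rate_), np.full(n, self.rate_)])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class MemorizingLearner(BaseEstimator, ClassifierMixin):
    """Outputs probability 1 exactly for rows it saw during training."""

    def fit(self, X, y):
        self.seen_ = {np.asarray(row, dtype=float).tobytes() for row in np.asarray(X)}
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = np.array(
            [
                1.0 if np.asarray(row, dtype=float).tobytes() in self.seen_ else 0.0
                for row in np.asarray(X)
            ]
        )
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class CoinFlipLearner(BaseEstimator, ClassifierMixin):
    """Emits label-independent pseudo-random probabilities (deterministic
    per input row, via a content hash) — a purely harmful base learner."""

    def __init__(self, seed=0):
        self.seed = seed

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = np.array([self._row_prob(row) for row in np.asarray(X, dtype=float)])
        return np.column_stack([1 - p, p])

    def _row_prob(self, row):
        digest = hashlib.sha256(row.tobytes() + str(self.seed).encode()).digest()
        return int.from_bytes(digest[:8], "big") / 2**64

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class ConstantLearner(BaseEstimator, ClassifierMixin):
    """Always emits the same positive probability."""

    def __init__(self, prob=1.0):
        self.prob = prob

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        n = np.asarray(X).shape[0]
        return np.column_stack([np.full(n, 1 - self.prob), np.full(n, self.prob)])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


register_learner("positive_rate", lambda spec: PositiveRateLearner())
register_learner("memorizer", lambda spec: MemorizingLearner())
register_learner("coin_flip", lambda spec: CoinFlipLearner(seed=spec.seed))
register_learner(
    "constant", lambda spec: ConstantLearner(**(spec.params or {"prob": 1.0}))
)


def _noise_encode(seq, spec):
    residues = seq.residues if hasattr(seq, "residues") else seq
    digest = hashlib.sha256(residues.encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "big"))
    return rng.random(8)


register_encoder("noise", "noise", _noise_encode, lambda L, spec: 8)

# A second registration of the one-hot encoder, for redundancy experiments.
register_encoder(
    "onehot_copy",
    "one-hot-copy",
    lambda s, spec: EncoderSpec("onehot").encode(s),
    lambda L, spec: 4 * L,
)


@pytest.fixture(scope="session")
def signal_dataset():
    """Strongly separable 41-nt data: positive PWM strength 0.8 vs uniform."""
    return generate_dataset(
        80, 80, make_pwm(41, 0.8, seed=0), make_pwm(41, 0.0, seed=1), seed=2
    )


@pytest.fixture(scope="session")
def null_dataset():
    """Both classes drawn from the identical uniform PWM."""
    pwm = make_pwm(41, 0.0, seed=0)
    return generate_dataset(80, 80, pwm, pwm, seed=3)


@pytest.fixture
def fast_base_specs():
    return [
        BaseLearnerSpec("logistic_regression", seed=0),
        BaseLearnerSpec("decision_tree", seed=0),
    ]


@pytest.fixture
def fast_final_spec():
    return BaseLearnerSpec("logistic_regression", seed=0)


@pytest.fixture
def onehot_eiip():
    return [EncoderSpec("onehot"), EncoderSpec("eiip")]
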