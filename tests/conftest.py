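"""Shared fixtures: one default-protocol synthetic session and the models
trained on it, built once per test run (they back several suites)."""

from __future__ import annotations

import numpy as np
import pytest

import emgrec as er

SESSION_SEED = 123


@pytest.fixture(scope="session")
def default_session():
    """Full default protocol: 50 repetitions x 6 motions, 70/30 split."""
    return er.make_session(er.SynthParams(), repetitions=50,
                           split_fraction=0.7, seed=SESSION_SEED)


@pytest.fixture(scope="session")
def prepared(default_session):
    return er.prepare_session(default_session)


@pytest.fixture(scope="session")
def train_windows(prepared):
    X, y = er.training_windows(prepared, per_trial=8)
    return X, y


@pytest.fixture(scope="session")
def trained_cnn(train_windows):
    X, y = train_windows
    return er.LwCNNClassifier(epochs=30, seed=0).fit(X, y)


@pytest.fixture(scope="session")
def trained_svm3(train_windows):
    X, y = train_windows
    return er.EmgSvmClassifier(feature_set="SVM3").fit(X, y)


@pytest.fixture(scope="session")
def small_session():
    """Quick 4-repetition session for structural tests."""
    return er.make_session(er.SynthParams(), repetitions=4, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
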