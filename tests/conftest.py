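"""Shared fixtures: small synthetic sessions reused across test modules.

Sessions are generated once per test run (session scope) because
generation plus preprocessing is the expensive part of most tests.
"""

import numpy as np
import pytest

from hemicycle import GeneratorConfig, compute_rate_tensors, generate_session


@pytest.fixture(scope="session")
def small_config():
    # Orthogonal arm subspaces so the same fixture serves recovery tests.
    return GeneratorConfig(n_units_per_hemisphere=25, n_muscles_per_arm=3,
                           n_trials_per_condition=16, subspace_overlap=0.0,
                           seed=42)


@pytest.fixture(scope="session")
def small_session(small_config):
    session, truth = generate_session(small_config)
    return session, truth


@pytest.fixture(scope="session")
def small_tensors(small_session):
    session, _ = small_session
    return compute_rate_tensors(session)


@pytest.fixture(scope="session")
def neural(small_tensors):
    return small_tensors[0]


@pytest.fixture(scope="session")
def emg(small_tensors):
    return small_tensors[1]


@pytest.fixture(scope="session")
def study_scale_tensors():
    """Study-scale session: a realistically sized population (200 units
    pooled, 40 trials/condition) with orthogonal arm subspaces.  Used by the
    recovery tests whose expected effect sizes assume realistic sampling
    noise (subspace capture, wrong-arm decoding, tangling comparison)."""
    cfg = GeneratorConfig(n_units_per_hemisphere=100, n_muscles_per_arm=6,
                          n_trials_per_condition=40, subspace_overlap=0.0,
                          seed=5)
    session, truth = generate_session(cfg)
    neural, emg = compute_rate_tensors(session)
    return neural, emg, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
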