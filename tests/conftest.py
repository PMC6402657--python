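"""Shared fixtures: seeded RNGs, random SPD matrices, synthetic sessions.

Session-scoped synthetic sessions are generated once and shared between the
pipeline and acceptance tests; channel counts and trial numbers are scaled
down from the full 60-channel protocol so the whole suite stays fast while
exercising the same code paths.
"""

import numpy as np
import pytest

from riembci.pipeline import PipelineConfig, adapt_session
from riembci.synth import GeneratorConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, n, scale=1.0):
    A = rng.standard_normal((n, n))
    return scale * (A @ A.T + n * np.eye(n))


@pytest.fixture
def spd_factory(rng):
    return lambda n, scale=1.0: random_spd(rng, n, scale)


SMALL = dict(n_channels=16, trials_per_class=5, dispersion=0.2, drift=0.05)


@pytest.fixture(scope="session")
def pipeline_config():
    # 8 CSP components suffice for the 16-channel test sessions
    return PipelineConfig(d=8, shrinkage=1e-4)


@pytest.fixture(scope="session")
def separable_session():
    """High-separation drift-free-ish session: 4 runs, 16 channels."""
    cfg = GeneratorConfig(n_runs=4, separation=1.0, seed=7, **SMALL)
    session, truth = generate_session(cfg)
    return session, truth, cfg


@pytest.fixture(scope="session")
def chance_session():
    """Zero-separation session: class labels carry no information.

    Predictions at chance are correlated within trials, so the held-out
    accuracy estimate needs many independent trials: full 40-trial runs and
    two held-out runs keep its standard error below 5 points.  Class-wise
    prototype drift is off — classes drifting along distinct directions is
    itself class information.
    """
    cfg = GeneratorConfig(
        n_channels=16, trials_per_class=10, dispersion=0.2, drift=0.0,
        n_runs=5, separation=0.0, seed=11,
    )
    session, truth = generate_session(cfg)
    return session, truth, cfg


@pytest.fixture(scope="session")
def adapted_separable(separable_session, pipeline_config):
    """Pipeline adapted through runs 0-2 of the separable session."""
    session, truth, cfg = separable_session
    return adapt_session(session, pipeline_config, seed=1, n_runs=3)


@pytest.fixture(scope="session")
def adapted_chance(chance_session, pipeline_config):
    session, truth, cfg = chance_session
    return adapt_session(session, pipeline_config, seed=1, n_runs=3)
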