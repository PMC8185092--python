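"""Shared synthetic-session fixtures.

Heavy sessions are session-scoped so the generator runs once per test
process; all generation is seeded and deterministic.
"""

import numpy as np
import pytest

from placeseq.preprocess import compute_rate_map
from placeseq.session import TaskGeometry
from placeseq.synth import SimulationSpec, build_session


@pytest.fixture(scope="session")
def geometry():
    return TaskGeometry()


def small_spec(**kw):
    """A short session spec: 3 pairs, brief rests, fixed seed."""
    defaults = dict(
        n_pairs=3,
        n_pre_laps=4,
        n_post_trials=2,
        rest_within_pair=10.0,
        rest_between_pairs=12.0,
        rest_between_stages=12.0,
        seed=42,
    )
    defaults.update(kw)
    return SimulationSpec(**defaults)


@pytest.fixture(scope="session")
def small_session(geometry):
    """Short session without LFP: trajectory, spikes, trials, truth."""
    session, truth = build_session(geometry, small_spec(), with_lfp=False)
    return session, truth


@pytest.fixture(scope="session")
def small_session_lfp(geometry):
    """Short session with LFP and planted replay, for LFP/SWR tests."""
    session, truth = build_session(
        geometry, small_spec(seed=7, replay_end_bias=1.0), with_lfp=True
    )
    return session, truth


@pytest.fixture(scope="session")
def trained_maps(small_session, geometry):
    """Rate maps estimated on everything after pre-running."""
    session, _ = small_session
    _, pre1 = session.stage_window("pre-running")
    return compute_rate_map(
        session.spikes,
        session.position,
        epoch=(pre1, float(session.position.times[-1])),
        restbox_angle=geometry.restbox_angle,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
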