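"""Shared fixtures: one fully simulated session reused across test modules."""

import numpy as np
import pytest

from crowdtrack import (
    DisplayGeometry,
    ObserverModel,
    merge_logs,
    simulate_session_logs,
)


@pytest.fixture(scope="session")
def geometry():
    return DisplayGeometry()


@pytest.fixture(scope="session")
def default_logs():
    """A complete 140-trial session of the default observer."""
    rng = np.random.default_rng(1234)
    return simulate_session_logs(ObserverModel(), rng=rng)


@pytest.fixture(scope="session")
def merged_default(default_logs):
    """Fused timeline of the default session (no offset correction)."""
    return merge_logs(default_logs.frames, default_logs.gaze, default_logs.geometry)
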