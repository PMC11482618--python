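import numpy as np
import pytest

from ethotrace import (
    Behavior,
    BoxConstraint,
    EthogramConfig,
    KeypointTrack,
    ZoneRule,
    default_config,
)


@pytest.fixture(scope="session")
def cfg():
    """The bundled elephant night-ethogram configuration."""
    return default_config()


@pytest.fixture
def tiny_cfg():
    """A minimal two-rule config over one body part, easy to reason about.

    Box A = x in [0, 10], box B = x in [20, 30], both y in [0, 10];
    'Rest' is the default.
    """
    return EthogramConfig(
        behaviors=[
            Behavior("Rest", is_default=True),
            Behavior("A"),
            Behavior("B"),
        ],
        zone_rules=[
            ZoneRule("A", priority=0, constraints=(BoxConstraint("tip", 0, 10, 0, 10),)),
            ZoneRule("B", priority=1, constraints=(BoxConstraint("tip", 20, 30, 0, 10),)),
        ],
        bodyparts=["tip", "base"],
        anchor_bodyparts=["base"],
        fps=5.0,
        p_cutoff=0.5,
    )


def random_track(rng, n_frames, bodyparts, fps=25.0,
                 missing_p=0.1, low_p=0.1):
    """Random rectangular track with some missing and low-likelihood cells."""
    k = len(bodyparts)
    x = rng.uniform(0, 1920, (n_frames, k))
    y = rng.uniform(0, 1080, (n_frames, k))
    lk = rng.uniform(0.5, 1.0, (n_frames, k))
    low = rng.random((n_frames, k)) < low_p
    lk[low] = rng.uniform(0.0, 0.499, low.sum())
    miss = rng.random((n_frames, k)) < missing_p
    for arr in (x, y, lk):
        arr[miss] = np.nan
    return KeypointTrack(list(bodyparts), x, y, lk, fps)
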