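import numpy as np
import pytest

from antquorum import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording():
    """A tagged 36-ant recording with 12 identical mid-range perturbations.

    Session-scoped: several test modules read from it (features, response
    measures, ground-truth consistency). Mid-range temperature so that both
    collective outcomes occur.
    """
    rng = np.random.default_rng(2024)
    arena = sd.ArenaSpec(frame_rate=1.0)
    schedule = sd.make_protocol(
        np.full(12, 34.0), rng, interval_s=2400.0, permute=False
    )
    colony = sd.ColonyParams()
    blobs, ants, gt = sd.generate_recording(arena, schedule, colony, rng)
    return {
        "arena": arena,
        "schedule": schedule,
        "colony": colony,
        "blobs": blobs,
        "ants": ants,
        "gt": gt,
    }
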