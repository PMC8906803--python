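import numpy as np
import pytest
from hypothesis import settings

import oroflow as of

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def carp_world():
    """One noisy carp-preset synthetic sequence."""
    return of.generate_feeding_sequence(of.CARP, n_cycles=3, seed=11)


@pytest.fixture(scope="session")
def carp_world_clean():
    """Noise-free carp sequence (ground truth exactly recoverable)."""
    return of.generate_feeding_sequence(of.CARP, n_cycles=2, seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def carp_analyzed(carp_world):
    anat, vs, pt = of.analyze_world(carp_world)
    return carp_world, anat, vs, pt


@pytest.fixture(scope="session")
def carp_analyzed_clean(carp_world_clean):
    anat, vs, pt = of.analyze_world(carp_world_clean)
    return carp_world_clean, anat, vs, pt


def piecewise_velocity_series(frame_rate=750.0):
    """Hand-traceable piecewise-constant anteroposterior velocity program."""
    t = np.arange(int(round(1.45 * frame_rate))) / frame_rate
    v = np.where(
        t < 0.5, -3.0,
        np.where(t < 0.75, -80.0,
                 np.where(t < 1.05, 0.0, np.where(t < 1.25, 10.0, -15.0))),
    )
    values = np.column_stack([v, np.zeros_like(v), np.zeros_like(v)])
    return of.VelocitySeries(values=values, valid=np.ones(t.size, bool), frame_rate=frame_rate)
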