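import numpy as np
import pytest

from gsphere import (
    AccelSeries, BehaviourProgramme, BehaviourState, build_geodesic,
)

# postures used across tests: gravity vectors well inside level-3 facets
# (roll-0 pitch arcs lie exactly on icosahedron edges, which would split
# samples between adjacent facets)
INTERIOR_POSTURE = dict(pitch=-16.0, roll=18.0)
INTERIOR_POSTURE_B = dict(pitch=44.0, roll=18.0)


@pytest.fixture(scope="session")
def sphere3():
    return build_geodesic(3)


@pytest.fixture(scope="session")
def sphere2():
    return build_geodesic(2)


@pytest.fixture
def rng():
    return np.random.default_rng(20160923)


def random_unit_vectors(rng, n):
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


@pytest.fixture
def small_trace():
    """A 5-sample trace with a linear ramp on the surge axis."""
    return AccelSeries(t=np.arange(5) / 40.0, ax=np.arange(5.0),
                       ay=np.ones(5), az=np.zeros(5))


def three_state_programme(duration_s=600.0, seed=11, dwell_s=30.0, noise_sd=0.02):
    """Rest/walk share one posture (different dynamics); climb is 60 deg away."""
    states = [
        BehaviourState("rest", **INTERIOR_POSTURE, dyn_amplitude=0.1,
                       dyn_freq_hz=2.0, noise_sd=noise_sd),
        BehaviourState("walk", **INTERIOR_POSTURE, dyn_amplitude=0.6,
                       dyn_freq_hz=2.0, noise_sd=noise_sd),
        BehaviourState("climb", **INTERIOR_POSTURE_B, dyn_amplitude=0.1,
                       dyn_freq_hz=2.0, noise_sd=noise_sd),
    ]
    return BehaviourProgramme(states=states, duration_s=duration_s, rate_hz=40.0,
                              dwell_s=dwell_s, seed=seed)
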