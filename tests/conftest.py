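import numpy as np
import pytest

from quatgeo import quatcore as qc
from quatgeo.preprocess import OrientationTrajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_trajectory(rng):
    """Factory for random smooth-ish trajectories (concatenated geodesic legs)."""

    def make(n_samples=50, n_legs=3, rate=100.0, generator=None):
        g = generator if generator is not None else rng
        waypoints = qc.random_quaternion(g, n_legs + 1)
        per_leg = max(n_samples // n_legs, 2)
        qs = [waypoints[0][None, :]]
        for a, b in zip(waypoints[:-1], waypoints[1:]):
            h = np.linspace(0, 1, per_leg + 1)[1:]
            qs.append(qc.geodesic(a, b, h))
        q = np.concatenate(qs, axis=0)
        t = np.arange(len(q)) / rate
        return OrientationTrajectory(t, q, rate=rate)

    return make


def sampled_geodesic(q1, qN, n=100, rate=None):
    """Uniform h-grid samples of the geodesic q1 -> qN as a trajectory."""
    h = np.linspace(0.0, 1.0, n)
    q = qc.geodesic(q1, qN, h)
    r = rate if rate is not None else float(n - 1)
    return OrientationTrajectory(np.arange(n) / r, q, rate=r)
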