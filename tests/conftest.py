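import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wigwag as w

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def rect_field():
    return w.named_field("rect30x60")


@pytest.fixture
def circle_field():
    return w.named_field("circle90")


@pytest.fixture
def donut_field():
    return w.named_field("donut")


@pytest.fixture
def circle_partition(circle_field):
    return w.partition_regions(circle_field)


@pytest.fixture
def rect_partition(rect_field):
    return w.partition_regions(rect_field)


@pytest.fixture
def intact_params():
    return w.preset_params("intact").params


class StubRng:
    """Deterministic stand-in for a Generator with scripted draws."""

    def __init__(self, normals=(), lognormals=(), integers=0, uniforms=()):
        self._normals = list(normals)
        self._lognormals = list(lognormals)
        self._integers = integers
        self._uniforms = list(uniforms)

    def normal(self, *a, **k):
        return self._normals.pop(0)

    def lognormal(self, *a, **k):
        return self._lognormals.pop(0)

    def integers(self, n):
        return self._integers % n

    def uniform(self, lo, hi):
        return self._uniforms.pop(0) if self._uniforms else lo


@pytest.fixture
def stub_rng_factory():
    return StubRng


def make_trajectory(positions, dt=0.1, field=None):
    positions = np.asarray(positions, dtype=float)
    times = np.arange(len(positions)) * dt
    return w.Trajectory(times=times, positions=positions, field=field)


@pytest.fixture
def toy_trajectory_factory():
    return make_trajectory
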