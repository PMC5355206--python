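import math

import pytest
from hypothesis import settings

import spiralsurvey as ss

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def camera() -> ss.CameraModel:
    """Reference imaging configuration: 42/34 degree fields of view, 2 Hz."""
    return ss.reference_camera()


@pytest.fixture(scope="session")
def drum() -> ss.DrumLine:
    """Reference drum and line: 0.16 m diameter, 6 m line."""
    return ss.reference_drum()


@pytest.fixture(scope="session")
def fixture_set() -> ss.FixtureSet:
    """The paired spiral/lawn scenario set, generated once per session."""
    return ss.generate_fixtures(seed=0)


@pytest.fixture(scope="session")
def spiral_report(fixture_set, camera) -> ss.CoverageReport:
    graph = ss.build_link_graph(fixture_set["spiral_ideal"], camera)
    return ss.coverage_metric(graph)


@pytest.fixture(scope="session")
def lawn_holes_report(fixture_set, camera) -> ss.CoverageReport:
    graph = ss.build_link_graph(fixture_set["lawn_holes"], camera)
    return ss.coverage_metric(graph)


@pytest.fixture(scope="session")
def small_camera() -> ss.CameraModel:
    """Same optics at a slower frame rate, for quick small trajectories."""
    return ss.CameraModel(
        beta_across=math.radians(42.0), beta_along=math.radians(34.0), frame_period=0.5
    )
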