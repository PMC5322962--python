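"""Shared fixtures: a coarse phantom/dose setup small enough for fast tests.

All stochastic fixtures are seeded; session scope avoids recomputing the
stand-in engine doses for every test.
"""

from __future__ import annotations

import numpy as np
import pytest

import vmat4d as v


@pytest.fixture(scope="session")
def arc() -> v.ArcSpec:
    return v.ArcSpec()


@pytest.fixture(scope="session")
def phantom() -> v.PhantomModel:
    return v.build_phantom()


@pytest.fixture(scope="session")
def beam() -> v.BeamSpec:
    return v.BeamSpec(aperture=(20.0, 20.0))


@pytest.fixture(scope="session")
def density(phantom) -> v.DoseGrid:
    """Coarse (4 mm) density rasterization for engine tests."""
    return phantom.rasterize(spacing=4.0)


@pytest.fixture(scope="session")
def schedule30(arc) -> v.SegmentSchedule:
    return v.discretize_arc(arc, 5.0)


@pytest.fixture(scope="session")
def doses30(phantom, schedule30, beam, density) -> v.SegmentDoseSet:
    """30-segment stand-in dose set on the coarse grid."""
    return v.compute_segment_doses(phantom, schedule30, beam, density=density)


@pytest.fixture(scope="session")
def traj_1b() -> v.Trajectory:
    """Case-1b sinusoid (SI 20 mm, AP 10 mm peak-to-peak, T = 4.5 s) with
    generous margin for phase shifts."""
    return v.make_sinusoid(v.SCENARIOS["1b"], duration=80.0)


@pytest.fixture(scope="session")
def small_cfg() -> v.ExperimentConfig:
    """Experiment config scaled down for test runtime: coarse 4 mm dose grid,
    10 x 10 cm ROI, two scenarios."""
    return v.ExperimentConfig(
        scenarios=("1b", "1d"),
        delta_alpha_levels=(5.0, 150.0),
        ground_truth_level=5.0,
        grid_spacing=4.0,
        roi_size=100.0,
        seed=7,
    )
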