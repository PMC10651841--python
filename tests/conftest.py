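import numpy as np
import pytest

import clusterpose as cp
from clusterpose.pipeline import child_rng


@pytest.fixture(scope="session")
def gait60():
    """Three gait cycles at a reduced 60 Hz test rate (integer samples/cycle)."""
    return cp.generate_gait_kinematics(cp.GaitParameters(sample_rate=60.0))


@pytest.fixture(scope="session")
def thigh():
    return cp.build_frustum("thigh")


@pytest.fixture(scope="session")
def shank():
    return cp.build_frustum("shank")


@pytest.fixture(scope="session")
def thigh_sta(gait60):
    """One synthetic STA profile per quadrant at default thigh amplitude."""
    return [
        cp.synthesize_sta(q, "thigh", gait60, rng=child_rng(1, "sta", "thigh", q))
        for q in range(4)
    ]


@pytest.fixture(scope="session")
def zero_sta(gait60):
    return [cp.synthesize_sta(q, "thigh", gait60, amplitude=0.0, rng=q) for q in range(4)]


@pytest.fixture(scope="session")
def thigh_config(thigh):
    return cp.sample_marker_configuration(thigh, rng=child_rng(1, "config", "thigh", 0))


@pytest.fixture(scope="session")
def noisy_trial(thigh, thigh_config, gait60, thigh_sta):
    """STA-corrupted thigh trial."""
    return cp.simulate_trial(thigh, thigh_config, gait60, thigh_sta)


@pytest.fixture(scope="session")
def clean_trial(thigh, thigh_config, gait60, zero_sta):
    """Noise-free rigid thigh trial."""
    return cp.simulate_trial(thigh, thigh_config, gait60, zero_sta)


def reconstructed_cm(poses, calibration):
    """CM trajectory implied by a pose series: R(t) c_cal + t(t)."""
    c = np.asarray(calibration).mean(axis=0)
    return np.einsum("tij,j->ti", poses.rotations, c) + poses.translations


def rotation_angle_deg(r_a, r_b):
    """Geodesic angle (deg) between two rotation-matrix series."""
    rel = np.einsum("tij,tkj->tik", r_a, r_b)
    tr = np.clip((np.trace(rel, axis1=1, axis2=2) - 1.0) / 2.0, -1.0, 1.0)
    return np.degrees(np.arccos(tr))


def rotation_angle_small_deg(r_a, r_b):
    """Angle (deg) between near-identical rotations via the chordal distance.

    ``θ ≈ ‖R_a − R_b‖_F / √2`` is exact to third order and, unlike the
    arccos-of-trace formula, is not limited to ~1e-8 rad resolution by
    floating-point rounding of the trace.
    """
    d = np.linalg.norm(np.asarray(r_a) - np.asarray(r_b), axis=(-2, -1))
    return np.degrees(2 * np.arcsin(np.clip(d / (2 * np.sqrt(2.0)), -1, 1)))
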