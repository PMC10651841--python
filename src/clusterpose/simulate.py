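"""Synthetic gait driving and soft-tissue-artifact (STA) injection.

The simulation emulates treadmill walking: a planar two-segment leg (thigh
and shank) swings about a fixed hip, with smooth periodic hip and knee
flexion-extension profiles.  Virtual markers placed on the frustum surfaces
move exactly rigidly with their segment (the ground truth), and STA noise is
added as a quadrant-specific displacement expressed in the *segment-local*
frame — skin motion relative to bone — then rotated into the global frame.
Every marker in a given quadrant receives the same displacement regardless
of its exact position within the zone, mirroring quadrant-averaged
characteristic STA profiles.

STA displacement profiles are either synthesized (band-limited sums of
harmonics of normalized gait time with seeded random phases; larger default
amplitude on the thigh than the shank, as reported for walking) or loaded
from a CSV of measured displacements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import InvalidInputError, MarkerTrajectorySet, RigidPose
from .frustum import FrustumSegment, MarkerConfiguration

__all__ = [
    "GaitParameters",
    "GaitKinematics",
    "STAProfile",
    "SimulatedTrial",
    "generate_gait_kinematics",
    "synthesize_sta",
    "default_sta_amplitude",
    "load_sta_profiles",
    "simulate_trial",
]

# Per-axis RMS displacement amplitude (metres) of the synthetic STA, per
# segment.  Thigh STA is substantially larger than shank STA in walking.
DEFAULT_STA_AMPLITUDE = {"thigh": 0.012, "shank": 0.005}


def default_sta_amplitude(segment: str) -> float:
    return DEFAULT_STA_AMPLITUDE[segment]


# ---------------------------------------------------------------------------
# gait kinematics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitParameters:
    """Parameters of the stylized periodic walking driver.

    The knee flexion profile is a sum of two periodic (von-Mises-shaped)
    bumps: a small loading-response bump in early stance and a large swing
    bump.  The hip profile is a single cosine with maximum flexion at heel
    strike.  Motion is planar (pure flexion-extension) by default so the
    commanded knee profile is recovered exactly by a joint-angle
    decomposition of the generated poses.
    """

    cycle_duration: float = 1.0     # s per gait cycle
    n_cycles: int = 3
    sample_rate: float = 240.0      # Hz
    stance_fraction: float = 0.6    # toe-off at 60 % of the cycle
    hip_amplitude_deg: float = 20.0
    knee_stance_deg: float = 15.0   # loading-response bump peak
    knee_swing_deg: float = 60.0    # swing bump peak
    hip_height: float = 1.0         # hip joint height above ground, m
    thigh_hip_offset: float = 0.07  # hip centre above the thigh proximal face, m
    shank_knee_offset: float = 0.04 # knee centre above the shank proximal face, m


@dataclass
class GaitKinematics:
    """Rigid thigh and shank pose series over whole gait cycles."""

    times: np.ndarray                 # (N_T,) s
    thigh_rotations: np.ndarray       # (N_T, 3, 3)
    thigh_translations: np.ndarray    # (N_T, 3)
    shank_rotations: np.ndarray
    shank_translations: np.ndarray
    heel_strikes: np.ndarray          # sample indices
    toe_offs: np.ndarray              # sample indices
    normalized_time: np.ndarray       # percent of gait cycle, [0, 100)
    knee_profile_deg: np.ndarray      # commanded knee FE per sample
    params: GaitParameters

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]

    def poses_for(self, segment: str) -> tuple[np.ndarray, np.ndarray]:
        if segment == "thigh":
            return self.thigh_rotations, self.thigh_translations
        if segment == "shank":
            return self.shank_rotations, self.shank_translations
        raise InvalidInputError(f"unknown segment {segment!r}")


def _rot_y(angle_rad: np.ndarray) -> np.ndarray:
    """Batch rotation matrices about the global Y (medial-lateral) axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    out = np.zeros(angle_rad.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 1, 1] = 1.0
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def _periodic_bump(phase: np.ndarray, centre: float, kappa: float) -> np.ndarray:
    """Smooth periodic bump peaking at `centre` with unit height."""
    return np.exp(kappa * (np.cos(2 * np.pi * (phase - centre)) - 1.0))


def knee_flexion_profile(phase: np.ndarray, params: GaitParameters) -> np.ndarray:
    """Commanded knee flexion-extension (deg) as a function of gait phase."""
    phase = np.asarray(phase, dtype=float)
    return (
        params.knee_stance_deg * _periodic_bump(phase, 0.15, 60.0)
        + params.knee_swing_deg * _periodic_bump(phase, 0.72, 30.0)
    )


def hip_flexion_profile(phase: np.ndarray, params: GaitParameters) -> np.ndarray:
    """Commanded hip (thigh inclination) angle (deg), max flexion at heel strike."""
    return params.hip_amplitude_deg * np.cos(2 * np.pi * np.asarray(phase, dtype=float))


def generate_gait_kinematics(
    params: GaitParameters | None = None,
    thigh: FrustumSegment | None = None,
    shank: FrustumSegment | None = None,
) -> GaitKinematics:
    """Generate rigid thigh/shank pose series for whole gait cycles.

    The leg is a planar linkage: the hip centre is fixed in space (treadmill
    walking), the thigh rotates about the hip by the hip profile, and the
    shank rotates relative to the thigh by the knee profile.  Segment-local
    frames follow the frustum convention (origin at the distal joint centre,
    Z up the shaft); the thigh's hip point and the shank's knee point sit on
    the local Z axis just above the proximal face.
    """
    from .frustum import build_frustum  # local import to avoid cycle at import time

    params = params or GaitParameters()
    if params.sample_rate <= 0:
        raise InvalidInputError("sample rate must be positive")
    if not 0 < params.stance_fraction < 1:
        raise InvalidInputError("stance fraction must lie in (0, 1)")
    thigh = thigh or build_frustum("thigh")
    shank = shank or build_frustum("shank")

    n_per_cycle = int(round(params.cycle_duration * params.sample_rate))
    n_t = params.n_cycles * n_per_cycle + 1
    times = np.arange(n_t) / params.sample_rate
    phase = (times / params.cycle_duration) % 1.0
    # the final sample closes the last cycle: phase 0 == phase 100 %
    normalized_time = phase * 100.0

    hip_deg = hip_flexion_profile(phase, params)
    knee_deg = knee_flexion_profile(phase, params)
    theta_thigh = np.radians(hip_deg)
    theta_shank = theta_thigh + np.radians(knee_deg)

    r_thigh = _rot_y(theta_thigh)
    r_shank = _rot_y(theta_shank)

    hip_global = np.array([0.0, 0.0, params.hip_height])
    hip_local = np.array([0.0, 0.0, thigh.h + params.thigh_hip_offset])
    knee_local_shank = np.array([0.0, 0.0, shank.h + params.shank_knee_offset])

    t_thigh = hip_global - r_thigh @ hip_local
    knee_global = t_thigh  # thigh local origin is the knee centre
    t_shank = knee_global - r_shank @ knee_local_shank

    heel_strikes = np.arange(0, n_t, n_per_cycle)
    toe_offs = (
        heel_strikes[:-1] + int(round(params.stance_fraction * n_per_cycle))
    )
    return GaitKinematics(
        times=times,
        thigh_rotations=r_thigh,
        thigh_translations=t_thigh,
        shank_rotations=r_shank,
        shank_translations=t_shank,
        heel_strikes=heel_strikes,
        toe_offs=toe_offs,
        normalized_time=normalized_time,
        knee_profile_deg=knee_deg,
        params=params,
    )


# ---------------------------------------------------------------------------
# STA profiles
# ---------------------------------------------------------------------------


@dataclass
class STAProfile:
    """Quadrant-specific STA displacement in the segment-local frame."""

    quadrant_id: int
    displacement: np.ndarray  # (N_T, 3) metres, segment-local frame
    amplitude: float = 0.0    # per-axis RMS scale, metres
    harmonics: int = 0
    max_step: float = 0.02    # continuity bound between adjacent samples, m

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        steps = np.linalg.norm(np.diff(self.displacement, axis=0), axis=1)
        if steps.size and steps.max() > self.max_step:
            raise InvalidInputError(
                f"STA profile discontinuous: max step {steps.max():g} m "
                f"exceeds bound {self.max_step:g} m"
            )


def synthesize_sta(
    quadrant_id: int,
    segment: str,
    gait: GaitKinematics,
    amplitude: float | None = None,
    harmonics: int = 3,
    rng: np.random.Generator | int | None = None,
) -> STAProfile:
    """Synthesize a continuous, gait-phase-locked STA displacement profile.

    Each axis is a sum of up to ``harmonics`` sinusoids of normalized gait
    time with seeded random phases and 1/k-decaying random weights,
    normalized so the per-axis RMS equals ``amplitude`` times a random
    per-axis factor in [0.5, 1].  RMS displacement therefore scales exactly
    linearly in ``amplitude``.
    """
    if amplitude is None:
        amplitude = DEFAULT_STA_AMPLITUDE[segment]
    if amplitude < 0:
        raise InvalidInputError("amplitude must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    phase = gait.normalized_time / 100.0
    disp = np.zeros((gait.n_samples, 3))
    axis_scale = rng.uniform(0.5, 1.0, size=3)
    for axis in range(3):
        u = np.zeros_like(phase)
        for k in range(1, harmonics + 1):
            w = rng.normal(0.0, 1.0 / k)
            psi = rng.uniform(0.0, 2 * np.pi)
            u = u + w * np.sin(2 * np.pi * k * phase + psi)
        rms = float(np.sqrt(np.mean(u**2)))
        if rms > 0:
            disp[:, axis] = amplitude * axis_scale[axis] * u / rms
    return STAProfile(quadrant_id, disp, amplitude=amplitude, harmonics=harmonics)


def load_sta_profiles(
    path,
    target_percent: np.ndarray,
) -> list[STAProfile]:
    """Load quadrant STA profiles from CSV and resample to a trial time base.

    The CSV has columns ``quadrant, percent_cycle, dx, dy, dz`` (metres);
    multiple rows per (quadrant, percent_cycle) — e.g. several physical
    markers assigned to the same quadrant — are averaged into one
    characteristic profile per quadrant.  Profiles are then linearly
    interpolated (periodic in the gait cycle) onto ``target_percent``.

    Raises an error listing any quadrant 0-3 absent from the file.
    """
    df = pd.read_csv(path)
    required = {"quadrant", "percent_cycle", "dx", "dy", "dz"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"STA CSV must have columns {sorted(required)}")
    present = set(int(q) for q in df["quadrant"].unique())
    missing = sorted(set(range(4)) - present)
    if missing:
        raise InvalidInputError(f"STA CSV missing quadrants: {missing}")
    target = np.asarray(target_percent, dtype=float) % 100.0
    profiles = []
    for q in range(4):
        sub = (
            df[df["quadrant"] == q]
            .groupby("percent_cycle", as_index=False)[["dx", "dy", "dz"]]
            .mean()
            .sort_values("percent_cycle")
        )
        pc = sub["percent_cycle"].to_numpy() % 100.0
        order = np.argsort(pc)
        pc = pc[order]
        vals = sub[["dx", "dy", "dz"]].to_numpy()[order]
        # periodic extension for wrap-around interpolation
        pc_ext = np.concatenate([pc - 100.0, pc, pc + 100.0])
        vals_ext = np.vstack([vals, vals, vals])
        disp = np.column_stack(
            [np.interp(target, pc_ext, vals_ext[:, a]) for a in range(3)]
        )
        profiles.append(STAProfile(q, disp))
    return profiles


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedTrial:
    """Ground-truth and STA-corrupted marker data for one configuration."""

    segment: str
    true_markers: MarkerTrajectorySet
    noisy_markers: MarkerTrajectorySet
    true_rotations: np.ndarray     # (N_T, 3, 3)
    true_translations: np.ndarray  # (N_T, 3)
    true_landmarks: dict[str, np.ndarray]  # name -> (N_T, 3) global
    landmarks_local: dict[str, np.ndarray]
    calibration_frame: int = 0

    @property
    def calibration_markers(self) -> np.ndarray:
        """STA-free marker positions at the static calibration sample."""
        return self.true_markers.positions[self.calibration_frame]

    def true_pose(self, i: int) -> RigidPose:
        return RigidPose(self.true_rotations[i], self.true_translations[i])


def simulate_trial(
    frustum: FrustumSegment,
    config: MarkerConfiguration,
    gait: GaitKinematics,
    sta_profiles: list[STAProfile],
    calibration_frame: int = 0,
) -> SimulatedTrial:
    """Drive a marker configuration through the gait and inject STA noise.

    True marker and landmark trajectories are exactly rigid.  The noisy
    trajectory adds, to every marker of quadrant ``q``, the same local-frame
    displacement ``d_q(t)`` rotated into the global frame by the segment's
    true rotation.
    """
    if len(sta_profiles) != 4:
        raise InvalidInputError("exactly one STA profile per quadrant is required")
    by_quadrant = {p.quadrant_id: p for p in sta_profiles}
    if set(by_quadrant) != {0, 1, 2, 3}:
        raise InvalidInputError("STA profiles must cover quadrants 0-3")
    rot, trans = gait.poses_for(frustum.name)
    n_t = gait.n_samples
    for p in sta_profiles:
        if p.displacement.shape[0] != n_t:
            raise InvalidInputError(
                "time-base mismatch between gait and STA profiles "
                f"({p.displacement.shape[0]} vs {n_t} samples)"
            )

    local = config.local_positions  # (4, 3)
    true = np.einsum("tij,mj->tmi", rot, local) + trans[:, None, :]
    disp_local = np.stack(
        [by_quadrant[int(q)].displacement for q in config.quadrant_ids], axis=1
    )  # (N_T, 4, 3)
    disp_global = np.einsum("tij,tmj->tmi", rot, disp_local)
    noisy = true + disp_global

    labels = config.labels
    true_set = MarkerTrajectorySet(labels, gait.times, true, gait.params.sample_rate)
    noisy_set = MarkerTrajectorySet(labels, gait.times, noisy, gait.params.sample_rate)

    landmarks = {
        name: np.einsum("tij,j->ti", rot, loc) + trans
        for name, loc in frustum.landmarks.items()
    }
    return SimulatedTrial(
        segment=frustum.name,
        true_markers=true_set,
        noisy_markers=noisy_set,
        true_rotations=rot,
        true_translations=trans,
        true_landmarks=landmarks,
        landmarks_local=dict(frustum.landmarks),
        calibration_frame=calibration_frame,
    )
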