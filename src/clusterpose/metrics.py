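"""Reconstruction-offset metrics, anatomical frames and knee angles.

Metrics compare a reference (ground-truth, noise-free) configuration R with
a reconstruction r produced by an estimator:

* **TRO** — centre-of-mass reconstruction offset ``‖T^R(t) − T^r(t)‖``.
* **eRO** — eigenvector reconstruction offset, the arccos of the (sign
  aligned, domain-clipped) dot product between reference and reconstructed
  principal axes, per eigenvector index.
* **ALRO** — anatomical-landmark reconstruction offset per landmark.
* **AFOO** — anatomical-frame origin offset.
* **KAO** — knee-angle offset (reconstructed minus true) per joint angle.

Knee angles use the floating-axis joint coordinate system: flexion about
the femoral medial-lateral axis, internal-external rotation about the
tibial longitudinal axis, ab-adduction about the mutual floating axis.
Gait phases are bounded by heel strike and toe-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InvalidInputError, RigidPose, transform_points

__all__ = [
    "AnatomicalFrame",
    "MetricSeries",
    "PhaseSummary",
    "tro",
    "ero",
    "reconstruct_landmarks",
    "alro",
    "anatomical_frame",
    "knee_angles",
    "knee_angle_series",
    "afoo",
    "kao",
    "phase_partition",
    "summarize",
    "config_spread",
]


@dataclass
class AnatomicalFrame:
    """Segment anatomical frame: origin + proper-rotation axes (columns)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)


@dataclass
class MetricSeries:
    """One metric time series for one (method, segment, configuration)."""

    name: str
    values: np.ndarray
    units: str
    method: str = ""
    segment: str = ""
    config_id: int = -1


@dataclass
class PhaseSummary:
    """Mean ± std of a metric pooled over configurations, per gait phase."""

    mean: dict[str, float]  # keys GC, StP, SwP
    std: dict[str, float]


def tro(t_ref: np.ndarray, t_rec: np.ndarray, **meta) -> MetricSeries:
    """Centre-of-mass reconstruction offset per step (metres)."""
    a, b = np.asarray(t_ref, float), np.asarray(t_rec, float)
    if a.shape != b.shape:
        raise InvalidInputError("series lengths differ")
    return MetricSeries("TRO", np.linalg.norm(a - b, axis=1), "m", **meta)


def ero(e_ref: np.ndarray, e_rec: np.ndarray, n: int, **meta) -> MetricSeries:
    """Eigenvector reconstruction offset (degrees) for eigenvector index n.

    The reconstructed vector is sign-aligned (flipped if the dot product is
    negative) and the dot product clipped into [-1, 1] before the arccos, so
    eigenvector sign ambiguity and rounding cannot produce spurious angles
    or domain errors.
    """
    a = np.asarray(e_ref, float)
    b = np.asarray(e_rec, float)
    dots = np.einsum("ti,ti->t", a, b)
    b = np.where(dots[:, None] < 0, -b, b)  # sign alignment
    # the arccos of the clipped dot, evaluated in the equivalent
    # half-chord form, which stays accurate for nearly parallel vectors
    chord = np.linalg.norm(a - b, axis=1)
    angles = 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
    return MetricSeries(f"eRO{n}", np.degrees(angles), "deg", **meta)


def reconstruct_landmarks(
    calibration_landmarks: dict[str, np.ndarray],
    rotations: np.ndarray,
    translations: np.ndarray,
) -> dict[str, np.ndarray]:
    """Map calibration-frame landmark positions through an estimated pose
    series: ``a(t) = R(t) a_cal + t(t)``."""
    out = {}
    for name, a_cal in calibration_landmarks.items():
        out[name] = np.einsum("tij,j->ti", rotations, np.asarray(a_cal, float)) + translations
    return out


def alro(true_landmark: np.ndarray, rec_landmark: np.ndarray, name: str, **meta) -> MetricSeries:
    """Anatomical-landmark reconstruction offset per step (metres)."""
    a, b = np.asarray(true_landmark, float), np.asarray(rec_landmark, float)
    if a.shape != b.shape:
        raise InvalidInputError("series lengths differ")
    return MetricSeries(f"ALRO:{name}", np.linalg.norm(a - b, axis=1), "m", **meta)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise InvalidInputError(f"degenerate landmark set: {what}")
    return v / n


def anatomical_frame(landmarks: dict[str, np.ndarray], segment: str) -> AnatomicalFrame:
    """Construct the segment anatomical frame from its four landmarks.

    Thigh: origin at the mid-epicondyle point, Z toward the femoral head,
    X along the cross product of the medial-to-lateral epicondyle line with
    Z (anterior), Y = Z x X (lateral).  Shank: origin at the mid-malleolus
    point, Z toward the HF-TT midpoint, analogous construction from the
    malleoli.  On the untransformed frustum template the frame coincides
    with the segment-local axes.
    """
    lm = {k: np.asarray(v, dtype=float) for k, v in landmarks.items()}
    if segment == "thigh":
        required = {"ME", "LE", "FH"}
        if not required.issubset(lm):
            raise InvalidInputError(f"thigh frame requires landmarks {sorted(required)}")
        origin = 0.5 * (lm["LE"] + lm["ME"])
        z = _unit(lm["FH"] - origin, "FH coincides with knee centre")
        ml = lm["LE"] - lm["ME"]
    elif segment == "shank":
        required = {"MM", "LM", "HF", "TT"}
        if not required.issubset(lm):
            raise InvalidInputError(f"shank frame requires landmarks {sorted(required)}")
        origin = 0.5 * (lm["LM"] + lm["MM"])
        z = _unit(0.5 * (lm["HF"] + lm["TT"]) - origin, "proximal point coincides with ankle centre")
        ml = lm["LM"] - lm["MM"]
    else:
        raise InvalidInputError(f"unknown segment {segment!r}")
    x = np.cross(ml, z)
    if np.linalg.norm(x) < 1e-12:
        raise InvalidInputError("degenerate landmark set: ML line parallel to long axis")
    x = _unit(x, "frame X")
    y = np.cross(z, x)
    return AnatomicalFrame(origin, np.column_stack([x, y, z]))


def knee_angles(
    thigh_frame: AnatomicalFrame,
    shank_frame: AnatomicalFrame,
) -> tuple[float, float, float, bool]:
    """Floating-axis knee angles (FE, AA, IE) in degrees, plus a gimbal flag.

    Decomposes the femur-to-tibia relative rotation as an intrinsic
    Y (flexion-extension) - X' (ab-adduction) - Z'' (internal-external)
    sequence, which is the floating-axis joint coordinate system for frames
    with X anterior, Y medial-lateral, Z longitudinal.  The gimbal flag is
    set when ab-adduction approaches +-90 deg.
    """
    r = thigh_frame.axes.T @ shank_frame.axes
    sb = np.clip(-r[1, 2], -1.0, 1.0)
    aa = np.arcsin(sb)
    gimbal = bool(abs(abs(sb) - 1.0) < 1e-9)
    fe = np.arctan2(r[0, 2], r[2, 2])
    ie = np.arctan2(r[1, 0], r[1, 1])
    return float(np.degrees(fe)), float(np.degrees(aa)), float(np.degrees(ie)), gimbal


def knee_angle_series(
    thigh_frames: list[AnatomicalFrame],
    shank_frames: list[AnatomicalFrame],
) -> np.ndarray:
    """(N_T, 3) array of (FE, AA, IE) knee angles per step."""
    out = np.empty((len(thigh_frames), 3))
    for i, (tf, sf) in enumerate(zip(thigh_frames, shank_frames)):
        fe, aa, ie, _ = knee_angles(tf, sf)
        out[i] = (fe, aa, ie)
    return out


def afoo(true_frames: list[AnatomicalFrame], rec_frames: list[AnatomicalFrame], **meta) -> MetricSeries:
    """Anatomical-frame origin offset per step (metres)."""
    a = np.stack([f.origin for f in true_frames])
    b = np.stack([f.origin for f in rec_frames])
    return MetricSeries("AFOO", np.linalg.norm(a - b, axis=1), "m", **meta)


def kao(
    true_thigh: list[AnatomicalFrame],
    true_shank: list[AnatomicalFrame],
    rec_thigh: list[AnatomicalFrame],
    rec_shank: list[AnatomicalFrame],
    **meta,
) -> tuple[list[MetricSeries], np.ndarray, np.ndarray]:
    """Knee-angle offsets (reconstructed minus true) per angle and step.

    Returns the three offset series (FE, AA, IE) plus the raw true and
    reconstructed angle curves for plotting.
    """
    true_angles = knee_angle_series(true_thigh, true_shank)
    rec_angles = knee_angle_series(rec_thigh, rec_shank)
    diff = rec_angles - true_angles
    names = ["KAO:FE", "KAO:AA", "KAO:IE"]
    series = [MetricSeries(names[k], diff[:, k], "deg", **meta) for k in range(3)]
    return series, true_angles, rec_angles


def phase_partition(
    heel_strike: int, toe_off: int, next_heel_strike: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample masks (GC, StP, SwP) for one gait cycle.

    Stance runs from heel strike up to (excluding) toe-off; swing from
    toe-off up to (excluding) the next heel strike.  The masks are disjoint
    and their union is the full cycle.
    """
    if not heel_strike < toe_off < next_heel_strike:
        raise InvalidInputError("toe-off must lie strictly between heel strikes")
    n = next_heel_strike - heel_strike
    gc = np.ones(n, dtype=bool)
    stance = np.zeros(n, dtype=bool)
    stance[: toe_off - heel_strike] = True
    swing = ~stance
    return gc, stance, swing


def summarize(values_by_config: np.ndarray, stance_mask: np.ndarray) -> PhaseSummary:
    """Pooled mean ± std of a metric over (configuration x time-in-phase).

    ``values_by_config`` has shape (n_config, n_samples); the stance mask
    partitions samples into stance and swing.  Statistics pool all
    configuration-sample pairs within each phase.
    """
    v = np.asarray(values_by_config, dtype=float)
    stance_mask = np.asarray(stance_mask, dtype=bool)
    if v.ndim != 2 or v.shape[1] != stance_mask.shape[0]:
        raise InvalidInputError("values must be (n_config, n_samples) matching the mask")
    phases = {"GC": np.ones_like(stance_mask), "StP": stance_mask, "SwP": ~stance_mask}
    mean = {k: float(v[:, m].mean()) for k, m in phases.items()}
    std = {k: float(v[:, m].std()) for k, m in phases.items()}
    return PhaseSummary(mean, std)


def config_spread(values_by_config: np.ndarray, stance_mask: np.ndarray) -> PhaseSummary:
    """Mean ± std *across configurations* of per-configuration phase means.

    The std here is the across-configuration envelope of the phase-averaged
    metric (zero iff the metric is identical across configurations).
    """
    v = np.asarray(values_by_config, dtype=float)
    stance_mask = np.asarray(stance_mask, dtype=bool)
    phases = {"GC": np.ones_like(stance_mask), "StP": stance_mask, "SwP": ~stance_mask}
    per_config = {k: v[:, m].mean(axis=1) for k, m in phases.items()}
    mean = {k: float(x.mean()) for k, x in per_config.items()}
    std = {k: float(x.std()) for k, x in per_config.items()}
    return PhaseSummary(mean, std)
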