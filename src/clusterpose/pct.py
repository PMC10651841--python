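"""Classic Point Cluster Technique (PCT) bone pose estimator.

Markers are treated as point masses.  At each time step the marker masses
are adjusted so that the *norm* of the inertia-tensor eigenvalues (taken
about the mass-weighted centre of mass) matches the norm from a static
calibration; the pose is then read off the eigenvectors and the weighted CM
of the adjusted mass distribution.

Matching only the eigenvalue norm is a known weakness: with N markers the
zero set of the objective is an (N−2)-dimensional manifold (after fixing
the mass scale), so the optimizer can wander along it between time steps
and produce discontinuous CM / eigenvector trajectories, and clusters with
an axis of rotational symmetry have degenerate spectra for which the
eigenvector basis is undefined.  A validity screen flags such steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import (
    DegenerateSpectrumError,
    InvalidInputError,
    eigendecompose,
    inertia_tensor,
    weighted_cm,
)
from .core import MarkerTrajectorySet
from .svdls import PoseSeries

__all__ = ["PctConfig", "MassSeries", "pct_pose"]


@dataclass(frozen=True)
class PctConfig:
    mass_lower_bound: float = 1e-6
    degeneracy_tol: float = 1e-9
    # validity screen: a step is discontinuous if the CM jumps by more than
    # cm_jump_factor times the 95th-percentile frame-to-frame marker
    # displacement, or any eigenvector rotates more than eigvec_jump_deg
    # between adjacent steps
    cm_jump_factor: float = 5.0
    eigvec_jump_deg: float = 30.0
    ftol: float = 1e-14
    maxiter: int = 200


@dataclass
class MassSeries:
    """Per-step adjusted marker masses with optimizer diagnostics."""

    masses: np.ndarray      # (N_T, N)
    objective: np.ndarray   # (N_T,) squared eigenvalue-norm mismatch
    valid: np.ndarray       # (N_T,) bool
    reasons: list[str] = field(default_factory=list)


def _eigvals_about_cm(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    cm = weighted_cm(positions, masses)
    return np.linalg.eigvalsh(inertia_tensor(positions - cm, masses).matrix)


def pct_pose(
    calibration: np.ndarray,
    observed: MarkerTrajectorySet,
    config: PctConfig | None = None,
) -> tuple[PoseSeries, MassSeries]:
    """Estimate the pose series with the classic PCT.

    Per step, minimizes ``(‖λ(m, t)‖ − ‖λ₀‖)²`` over masses ``m`` subject to
    the gauge constraint ``Σ m = N`` and ``m ≥ mass_lower_bound``,
    warm-started from the previous step's solution (unit masses at the first
    step).  Eigen-quantities are computed about the mass-weighted CM; the
    pose rotation is ``E(t) E₀ᵀ`` (sign continuity enforced against the
    previous step) and the pose maps the calibration centroid to the
    weighted CM.

    Raises
    ------
    DegenerateSpectrumError
        If the calibration cluster itself has a (near-)repeated inertia
        eigenvalue — the rotational-symmetry case in which PCT is undefined.
    """
    config = config or PctConfig()
    cal = np.asarray(calibration, dtype=float)
    n = cal.shape[0]
    if n < 4:
        raise InvalidInputError("PCT requires at least 4 markers")
    cal_cm = cal.mean(axis=0)
    cal_eig = eigendecompose(
        inertia_tensor(cal - cal_cm), degeneracy_tol=config.degeneracy_tol
    )
    # make the calibration basis proper so continuity keeps det(R) = +1
    e_cal = cal_eig.eigenvectors.copy()
    if np.linalg.det(e_cal) < 0:
        e_cal[:, 2] = -e_cal[:, 2]
    target = float(np.linalg.norm(cal_eig.eigenvalues))

    n_t = observed.n_samples
    rot = np.empty((n_t, 3, 3))
    trans = np.empty((n_t, 3))
    rms = np.zeros(n_t)
    masses = np.empty((n_t, n))
    objective = np.empty(n_t)
    valid = np.ones(n_t, dtype=bool)
    reasons = [""] * n_t

    m_prev = np.ones(n)
    e_prev = e_cal
    cm_series = np.empty((n_t, 3))

    bounds = [(config.mass_lower_bound, None)] * n
    constraint = {"type": "eq", "fun": lambda m: m.sum() - n}

    for i in range(n_t):
        p = observed.positions[i]

        def obj(m: np.ndarray) -> float:
            return (np.linalg.norm(_eigvals_about_cm(p, m)) - target) ** 2

        res = minimize(
            obj,
            m_prev,
            method="SLSQP",
            bounds=bounds,
            constraints=[constraint],
            options={"ftol": config.ftol, "maxiter": config.maxiter},
        )
        m = res.x if res.success else m_prev
        if not res.success:
            valid[i] = False
            reasons[i] = f"optimizer: {res.message}"
        masses[i] = m
        objective[i] = obj(m)
        cm = weighted_cm(p, m)
        cm_series[i] = cm
        try:
            eig = eigendecompose(
                inertia_tensor(p - cm, m),
                reference=e_prev,
                degeneracy_tol=config.degeneracy_tol,
            )
            e_cur = eig.eigenvectors
        except DegenerateSpectrumError as exc:
            valid[i] = False
            reasons[i] = f"degenerate: {exc}"
            e_cur = e_prev
        if np.linalg.det(e_cur) < 0:
            # a flip slipped through sign continuity: improper basis
            valid[i] = False
            reasons[i] = reasons[i] or "improper eigenvector basis"
            e_cur = e_cur.copy()
            e_cur[:, 2] = -e_cur[:, 2]
        rot[i] = e_cur @ e_cal.T
        trans[i] = cm - rot[i] @ cal_cm
        rms[i] = float(
            np.sqrt(np.mean(np.sum(((cal @ rot[i].T + trans[i]) - p) ** 2, axis=1)))
        )
        m_prev = m
        e_prev = e_cur

    # discontinuity screen
    marker_steps = np.linalg.norm(np.diff(observed.positions, axis=0), axis=2)
    if marker_steps.size:
        step_scale = float(np.percentile(marker_steps, 95))
    else:
        step_scale = 0.0
    cm_jumps = np.linalg.norm(np.diff(cm_series, axis=0), axis=1)
    cos_lim = np.cos(np.radians(config.eigvec_jump_deg))
    for i in range(1, n_t):
        if step_scale > 0 and cm_jumps[i - 1] > config.cm_jump_factor * step_scale:
            valid[i] = False
            reasons[i] = reasons[i] or "CM discontinuity"
        # per-eigenvector rotation between adjacent steps
        dots = np.abs(np.sum((rot[i] @ e_cal) * (rot[i - 1] @ e_cal), axis=0))
        if np.any(dots < cos_lim):
            valid[i] = False
            reasons[i] = reasons[i] or "eigenvector discontinuity"

    poses = PoseSeries("PCT", rot, trans, rms, valid=valid.copy())
    mass_series = MassSeries(masses, objective, valid, reasons)
    return poses, mass_series
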