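"""SVD least-squares (Kabsch-type) rigid pose estimator.

At each time step the proper rotation R and translation t minimizing
``Σ_j ‖R a_j + t − b_j‖²`` between the static-calibration cluster ``a`` and
the observed cluster ``b`` are found from the SVD of the cross-dispersion
matrix of the mean-centred clusters, with the reflection corrected so that
det(R) = +1.  The optimal translation maps the calibration centroid onto
the observed centroid exactly — hence the estimated segment CM equals the
observed centroid, independent of the marker arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import InvalidInputError, MarkerTrajectorySet, RankDeficiencyError

__all__ = ["PoseSeries", "kabsch", "svdls_pose"]


@dataclass
class PoseSeries:
    """Per-time-step rigid pose estimates with diagnostics.

    The pose maps calibration-frame global coordinates x to time-t
    coordinates via ``R(t) x + t(t)``.
    """

    method: str
    rotations: np.ndarray       # (N_T, 3, 3)
    translations: np.ndarray    # (N_T, 3)
    rms_residuals: np.ndarray   # (N_T,) metres
    valid: np.ndarray = field(default=None)  # (N_T,) bool

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.rotations.shape[0], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.rotations.shape[0]


def kabsch(calibration: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rigid transform mapping `calibration` onto `observed`.

    Returns ``(R, t, rms)`` with ``R`` the proper rotation minimizing the
    mean-centred least-squares misfit (reflection corrected) and
    ``t = b̄ − R ā``, so ``R ā + t = b̄`` exactly.
    """
    a = np.asarray(calibration, dtype=float)
    b = np.asarray(observed, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InvalidInputError("point sets must both have shape (N, 3)")
    a_mean = a.mean(axis=0)
    b_mean = b.mean(axis=0)
    ac = a - a_mean
    bc = b - b_mean
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = b_mean - r @ a_mean
    rms = float(np.sqrt(np.mean(np.sum((a @ r.T + t - b) ** 2, axis=1))))
    return r, t, rms


def svdls_pose(calibration: np.ndarray, observed: MarkerTrajectorySet) -> PoseSeries:
    """Fit a rigid transform from the calibration cluster at every step.

    Raises
    ------
    RankDeficiencyError
        If the calibration cluster is (near-)collinear: the rotation about
        the cluster axis is then unobservable.
    """
    a = np.asarray(calibration, dtype=float)
    if a.shape[0] < 3:
        raise InvalidInputError("at least 3 markers are required")
    ac = a - a.mean(axis=0)
    sv = np.linalg.svd(ac, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-300):
        raise RankDeficiencyError("calibration cluster is collinear")
    n_t = observed.n_samples
    rot = np.empty((n_t, 3, 3))
    trans = np.empty((n_t, 3))
    rms = np.empty(n_t)
    for i in range(n_t):
        rot[i], trans[i], rms[i] = kabsch(a, observed.positions[i])
    return PoseSeries("SVD-LS", rot, trans, rms)
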