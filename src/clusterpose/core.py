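"""Shared rigid-body mathematics for marker-cluster pose estimation.

Conventions
-----------
* Positions are in metres, in a right-handed global frame.
* The inertia tensor of a marker cluster is the moment-of-inertia matrix of
  the markers treated as point masses, taken about the *origin of the frame
  the coordinates are expressed in* (no implicit centering).
* Eigenvalues are always reported in ascending order.  Eigenvector signs are
  fixed either against a reference decomposition (temporal continuity: the
  dot product with the reference column is made non-negative) or, absent a
  reference, by making the largest-magnitude component of each column
  positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidInputError",
    "DegenerateSpectrumError",
    "RankDeficiencyError",
    "MarkerTrajectorySet",
    "RigidPose",
    "InertiaTensor",
    "EigenDecomposition",
    "inertia_tensor",
    "eigendecompose",
    "centroid",
    "weighted_cm",
    "transform_points",
]


class InvalidInputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


class DegenerateSpectrumError(RuntimeError):
    """Raised when an inertia spectrum has a (near-)repeated eigenvalue.

    This is the rotational-symmetry failure mode: clusters with an axis of
    rotational symmetry have repeated principal moments, the eigenvector
    basis is not unique, and first-order eigenvector perturbation (which
    divides by eigenvalue gaps) is undefined.
    """


class RankDeficiencyError(RuntimeError):
    """Raised when a marker cluster is too degenerate (e.g. collinear)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MarkerTrajectorySet:
    """Labelled 3-D marker positions over time at a fixed sample rate.

    Attributes
    ----------
    labels : list of str
        Marker names, length ``N``.
    times : (N_T,) ndarray
        Sample times in seconds, strictly increasing.
    positions : (N_T, N, 3) ndarray
        Marker positions in metres.
    sample_rate : float
        Nominal sampling frequency in Hz.
    """

    labels: list[str]
    times: np.ndarray
    positions: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.sample_rate <= 0:
            raise InvalidInputError("sample_rate must be positive")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise InvalidInputError("positions must have shape (N_T, N, 3)")
        if self.positions.shape[0] != self.times.shape[0]:
            raise InvalidInputError("positions and times lengths differ")
        if self.positions.shape[1] != len(self.labels):
            raise InvalidInputError("positions and labels lengths differ")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidInputError("positions must be finite")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return len(self.labels)

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]

    def frame(self, i: int) -> np.ndarray:
        """Marker positions at sample ``i`` as an (N, 3) array."""
        return self.positions[i]


_ORTHO_TOL = 1e-10


@dataclass
class RigidPose:
    """Proper rotation + translation of a segment frame at one instant."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise InvalidInputError("pose must be a 3x3 rotation and 3-vector")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise InvalidInputError(f"rotation not orthonormal (err={err:g})")
        if abs(np.linalg.det(self.rotation) - 1.0) > _ORTHO_TOL:
            raise InvalidInputError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from the local into the global frame."""
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidPose":
        rt = self.rotation.T
        return RigidPose(rt, -rt @ self.translation)

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Return the pose ``self ∘ other`` (apply *other* first)."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class InertiaTensor:
    """3x3 symmetric moment-of-inertia matrix of a point-mass cluster."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise InvalidInputError("inertia tensor must be 3x3")
        scale = max(np.abs(self.matrix).max(), 1.0)
        if np.abs(self.matrix - self.matrix.T).max() > 1e-12 * scale:
            raise InvalidInputError("inertia tensor must be symmetric")


@dataclass
class EigenDecomposition:
    """Ascending eigenvalues and sign-fixed orthonormal eigenvectors."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns e_1, e_2, e_3

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)

    def reconstruct(self) -> np.ndarray:
        """Rebuild the tensor as ``E diag(λ) Eᵀ``."""
        e, v = self.eigenvalues, self.eigenvectors
        return (v * e) @ v.T


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def inertia_tensor(positions: np.ndarray, masses: np.ndarray | None = None) -> InertiaTensor:
    """Moment-of-inertia matrix of point masses about the coordinate origin.

    Parameters
    ----------
    positions : (N, 3) ndarray
        Point coordinates in metres.  The tensor is taken about the origin of
        this coordinate frame; pass centred coordinates for a centroidal
        tensor.
    masses : (N,) ndarray, optional
        Point masses; unit masses if omitted.
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise InvalidInputError("positions must have shape (N, 3)")
    if p.shape[0] < 3:
        raise InvalidInputError("at least 3 markers are required")
    if not np.all(np.isfinite(p)):
        raise InvalidInputError("positions must be finite")
    if masses is None:
        m = np.ones(p.shape[0])
    else:
        m = np.asarray(masses, dtype=float)
        if m.shape != (p.shape[0],):
            raise InvalidInputError("masses must be an N-vector")
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    ixx = np.sum(m * (y * y + z * z))
    iyy = np.sum(m * (x * x + z * z))
    izz = np.sum(m * (x * x + y * y))
    ixy = -np.sum(m * x * y)
    ixz = -np.sum(m * x * z)
    iyz = -np.sum(m * y * z)
    return InertiaTensor(np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]]))


def _fix_signs(vectors: np.ndarray, reference: np.ndarray | None) -> np.ndarray:
    v = vectors.copy()
    for j in range(3):
        if reference is not None:
            if np.dot(v[:, j], reference[:, j]) < 0:
                v[:, j] = -v[:, j]
        else:
            k = int(np.argmax(np.abs(v[:, j])))
            if v[k, j] < 0:
                v[:, j] = -v[:, j]
    return v


def eigendecompose(
    tensor: InertiaTensor | np.ndarray,
    reference: EigenDecomposition | np.ndarray | None = None,
    degeneracy_tol: float = 1e-9,
) -> EigenDecomposition:
    """Eigendecompose a symmetric tensor with fixed ordering and signs.

    Eigenvalues come out ascending.  If *reference* is given, each
    eigenvector column is flipped so that its dot product with the matching
    reference column is non-negative (temporal continuity); otherwise the
    largest-magnitude component of each column is made positive.

    Raises
    ------
    DegenerateSpectrumError
        If an adjacent eigenvalue gap falls below ``degeneracy_tol`` relative
        to the spectral scale.  Set ``degeneracy_tol=0`` to disable.
    """
    mat = tensor.matrix if isinstance(tensor, InertiaTensor) else np.asarray(tensor, dtype=float)
    w, v = np.linalg.eigh(mat)
    scale = max(float(np.abs(w).max()), np.finfo(float).tiny)
    if degeneracy_tol > 0:
        gaps = np.diff(w)
        if np.any(gaps < degeneracy_tol * scale):
            raise DegenerateSpectrumError(
                f"near-degenerate spectrum: eigenvalues {w}, relative gap "
                f"{gaps.min() / scale:g} below tolerance {degeneracy_tol:g}"
            )
    ref = None
    if reference is not None:
        ref = reference.eigenvectors if isinstance(reference, EigenDecomposition) else np.asarray(reference)
    return EigenDecomposition(w, _fix_signs(v, ref))


def centroid(positions: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the points (unit-mass centre of mass)."""
    p = np.asarray(positions, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 1:
        raise InvalidInputError("positions must have shape (N, 3) with N >= 1")
    return p.mean(axis=0)


def weighted_cm(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted centre of mass ``Σ m_j v_j / Σ m_j``."""
    p = np.asarray(positions, dtype=float)
    m = np.asarray(masses, dtype=float)
    total = m.sum()
    if total == 0:
        raise InvalidInputError("total mass must be nonzero")
    return (m[:, None] * p).sum(axis=0) / total


def transform_points(local: np.ndarray, pose: RigidPose) -> np.ndarray:
    """Apply ``rotation · x + translation`` to each point."""
    return pose.apply(local)
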