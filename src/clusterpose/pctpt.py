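"""PCT-PT: Point Cluster Technique extended with eigenvalue perturbation.

Pipeline per trial:

1. **Denoising** (per time step): the inertia tensor of the centred noisy
   cluster is driven iteratively toward the static-calibration eigenvalue
   spectrum λ₀ using first-order symmetric-matrix perturbation theory.  At
   each iteration a symmetric perturbation δI (parameterized by its six
   unique entries k₁…k₆) is found as the minimum-norm least-squares solution
   of the 3x6 system mapping k to the predicted eigenvalue changes
   ``δλ_j = e_jᵀ δI e_j``; the predicted eigenvector changes
   ``δe_j = Σ_{i≠j} (e_iᵀ δI e_j)/(λ_j − λ_i) e_i`` must remain small
   (near-orthogonal update, near-unit norm) for the step to be accepted,
   otherwise the step size s is halved; s < 2⁻¹³ aborts, ‖λ₀ − λ_C‖ < 10⁻⁷
   with mutually orthogonal eigenvectors succeeds.
2. **Mass recovery**: a single constant mass per marker is recovered by
   solving the stacked 6·N_T nonlinear equations equating the denoised
   tensors with the mass-weighted tensor of the measured positions
   (Levenberg-Marquardt from unit masses).
3. **CM constraint and reflection**: the mass-weighted CM is blended toward
   the centroid so its distance from the centroid never exceeds d_max, and
   the sign of its projection onto the first denoised eigenvector decides
   whether the CM estimate is reflected about the centroid.
4. **Orientation**: the mean-centred proper-rotation least-squares fit
   (identical to the SVD-LS rotation by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import (
    DegenerateSpectrumError,
    EigenDecomposition,
    InertiaTensor,
    InvalidInputError,
    MarkerTrajectorySet,
    centroid,
    eigendecompose,
    inertia_tensor,
    weighted_cm,
)
from .svdls import PoseSeries, kabsch

__all__ = [
    "PctPtConfig",
    "DenoiseResult",
    "MassDistribution",
    "CMResolution",
    "PctPtDiagnostics",
    "eig_perturbation_row",
    "solve_perturbation",
    "perturbation_matrix",
    "eigvec_offset",
    "denoise_inertia",
    "recover_masses",
    "constrain_cm",
    "resolve_cm_sign",
    "pctpt_pose",
]


@dataclass(frozen=True)
class PctPtConfig:
    eigvec_dot_tol: float = 1e-7      # acceptance: ‖e_jᵀ δe_j‖ bound
    eigvec_norm_tol: float = 1e-4     # acceptance: | ‖e_j + δe_j‖ − 1 | bound
    lambda_tol: float = 1e-7          # success: ‖λ₀ − λ_C‖ bound
    ortho_tol: float = 1e-7           # success: pairwise eigenvector dots
    s_min: float = 2.0 ** -13         # step-halving budget
    max_iterations: int = 500
    degeneracy_tol: float = 1e-9
    d_max: float = 0.01               # CM-to-centroid bound, metres
    zero_tol: float = 1e-12           # |ΔT| below this is treated as zero


# ---------------------------------------------------------------------------
# first-order perturbation primitives
# ---------------------------------------------------------------------------

# k ordering: (k1, k2, k3, k4, k5, k6) = (11, 12, 13, 22, 23, 33) entries
_K_INDEX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def perturbation_matrix(k: np.ndarray) -> np.ndarray:
    """Assemble the symmetric 3x3 perturbation from its six unique entries."""
    k1, k2, k3, k4, k5, k6 = np.asarray(k, dtype=float)
    return np.array([[k1, k2, k3], [k2, k4, k5], [k3, k5, k6]])


def eig_perturbation_row(e: np.ndarray) -> np.ndarray:
    """Row r with ``r · k = eᵀ δI(k) e`` for every perturbation vector k."""
    e = np.asarray(e, dtype=float)
    if abs(np.linalg.norm(e) - 1.0) > 1e-10:
        raise InvalidInputError("eigenvector must be unit norm")
    ex, ey, ez = e
    return np.array([ex * ex, 2 * ex * ey, 2 * ex * ez, ey * ey, 2 * ey * ez, ez * ez])


def solve_perturbation(eigenvectors: np.ndarray, d_lambda: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares k solving the 3x6 system A k = δλ."""
    a = np.vstack([eig_perturbation_row(eigenvectors[:, j]) for j in range(3)])
    dk, *_ = np.linalg.lstsq(a, np.asarray(d_lambda, dtype=float), rcond=None)
    return dk


def eigvec_offset(
    eigenvectors: np.ndarray,
    eigenvalues: np.ndarray,
    d_inertia: np.ndarray,
    degeneracy_tol: float = 1e-9,
) -> np.ndarray:
    """First-order eigenvector offsets δe_j for a symmetric perturbation.

    ``δe_j = Σ_{i≠j} (e_iᵀ δI e_j)/(λ_j − λ_i) e_i``; each offset is exactly
    orthogonal to its eigenvector.  Returns a 3x3 array with δe_j in
    column j.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    e = np.asarray(eigenvectors, dtype=float)
    di = np.asarray(d_inertia, dtype=float)
    scale = max(float(np.abs(lam).max()), np.finfo(float).tiny)
    offsets = np.zeros((3, 3))
    g = e.T @ di @ e
    for j in range(3):
        for i in range(3):
            if i == j:
                continue
            gap = lam[j] - lam[i]
            if abs(gap) < degeneracy_tol * scale:
                raise DegenerateSpectrumError(
                    f"eigenvalue gap |λ_{j+1} − λ_{i+1}| = {abs(gap):g} below tolerance"
                )
            offsets[:, j] += (g[i, j] / gap) * e[:, i]
    return offsets


# ---------------------------------------------------------------------------
# denoising loop
# ---------------------------------------------------------------------------


@dataclass
class DenoiseResult:
    tensor: InertiaTensor
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    converged: bool
    iterations: int
    final_s: float
    reason: str = ""


def _gram_schmidt(v: np.ndarray) -> np.ndarray:
    """Re-orthonormalize columns in index order."""
    out = v.copy()
    for j in range(3):
        for i in range(j):
            out[:, j] -= np.dot(out[:, i], out[:, j]) * out[:, i]
        nrm = np.linalg.norm(out[:, j])
        if nrm == 0:
            raise InvalidInputError("degenerate basis in re-orthonormalization")
        out[:, j] /= nrm
    return out


def denoise_inertia(
    initial: InertiaTensor | np.ndarray,
    lambda_0: np.ndarray,
    config: PctPtConfig | None = None,
    reference: EigenDecomposition | np.ndarray | None = None,
) -> DenoiseResult:
    """Iteratively drive a tensor's eigenvalues to λ₀ by perturbation steps.

    Failure (step-halving budget or iteration cap exhausted) is *returned*
    in the result, not raised; a degenerate spectrum propagates as
    :class:`DegenerateSpectrumError`.
    """
    config = config or PctPtConfig()
    lam0 = np.asarray(lambda_0, dtype=float)
    mat = initial.matrix if isinstance(initial, InertiaTensor) else np.asarray(initial, float)
    eig = eigendecompose(mat, reference=reference, degeneracy_tol=config.degeneracy_tol)
    lam = eig.eigenvalues.copy()
    vecs = eig.eigenvectors.copy()

    s = 1.0
    iterations = 0

    def _success() -> bool:
        if np.linalg.norm(lam0 - lam) >= config.lambda_tol:
            return False
        dots = vecs.T @ vecs - np.eye(3)
        return bool(np.abs(dots).max() < config.ortho_tol)

    while iterations < config.max_iterations:
        if _success():
            tensor = InertiaTensor((vecs * lam) @ vecs.T)
            return DenoiseResult(tensor, lam, vecs, True, iterations, s)
        d_lambda = s * (lam0 - lam)
        dk = solve_perturbation(vecs, d_lambda)
        di = perturbation_matrix(dk)
        d_vecs = eigvec_offset(vecs, lam, di, config.degeneracy_tol)
        iterations += 1
        dot_ok = all(
            abs(np.dot(vecs[:, j], d_vecs[:, j])) < config.eigvec_dot_tol for j in range(3)
        )
        norm_ok = all(
            abs(np.linalg.norm(vecs[:, j] + d_vecs[:, j]) - 1.0) < config.eigvec_norm_tol
            for j in range(3)
        )
        if dot_ok and norm_ok:
            lam = lam + d_lambda
            vecs = _gram_schmidt(vecs + d_vecs)
            s = 1.0
        else:
            s *= 0.5
            if s < config.s_min:
                tensor = InertiaTensor((vecs * lam) @ vecs.T)
                return DenoiseResult(
                    tensor, lam, vecs, False, iterations, s,
                    reason="step size fell below 2^-13",
                )
    tensor = InertiaTensor((vecs * lam) @ vecs.T)
    converged = _success()
    return DenoiseResult(
        tensor, lam, vecs, converged, iterations, s,
        reason="" if converged else "iteration cap reached",
    )


# ---------------------------------------------------------------------------
# mass recovery
# ---------------------------------------------------------------------------


@dataclass
class MassDistribution:
    masses: np.ndarray
    residual_norm: float
    converged: bool
    negative_masses: bool = False


def _unit_inertia_entries(p: np.ndarray) -> np.ndarray:
    """Six unique inertia entries contributed by each unit-mass point.

    Returns a (6, N) array in the (11, 12, 13, 22, 23, 33) ordering.
    """
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    return np.stack([y * y + z * z, -x * y, -x * z, x * x + z * z, -y * z, x * x + y * y])


def recover_masses(
    tensors: np.ndarray | list[InertiaTensor],
    positions: np.ndarray | MarkerTrajectorySet,
) -> MassDistribution:
    """Recover one constant mass per marker from denoised tensor series.

    Stacks the six unique tensor entries for every time step (6·N_T
    equations in N unknowns) and solves with Levenberg-Marquardt from unit
    masses.  The system is linear in the masses, so the (constant) Jacobian
    is supplied analytically.
    """
    if isinstance(positions, MarkerTrajectorySet):
        pos = positions.positions
    else:
        pos = np.asarray(positions, dtype=float)
    if isinstance(tensors, (list, tuple)):
        tens = np.stack([t.matrix if isinstance(t, InertiaTensor) else t for t in tensors])
    else:
        tens = np.asarray(tensors, dtype=float)
    n_t, n = pos.shape[0], pos.shape[1]
    if n < 4:
        raise InvalidInputError("mass recovery requires at least 4 markers")
    if tens.shape[0] != n_t:
        raise InvalidInputError("tensor and position series lengths differ")

    jac = np.concatenate([_unit_inertia_entries(pos[k]).reshape(6, n) for k in range(n_t)])
    target = np.concatenate([[tens[k][i, j] for (i, j) in _K_INDEX] for k in range(n_t)])

    def fun(m: np.ndarray) -> np.ndarray:
        return jac @ m - target

    m0 = np.ones(n)
    res = least_squares(fun, m0, jac=lambda m: jac, method="lm")
    masses = res.x
    resid = float(np.linalg.norm(fun(masses)))
    converged = bool(res.success) and resid <= float(np.linalg.norm(fun(m0))) + 1e-12
    return MassDistribution(masses, resid, converged, negative_masses=bool(np.any(masses < 0)))


# ---------------------------------------------------------------------------
# CM constraint + reflection
# ---------------------------------------------------------------------------


@dataclass
class CMResolution:
    alpha: float
    t_unconstrained: np.ndarray   # (N_T, 3)
    t_constrained: np.ndarray     # (N_T, 3)
    t_final: np.ndarray | None    # (N_T, 3); None until sign resolution
    delta_t: np.ndarray | None    # (N_T,) projection onto e_F1
    centroids: np.ndarray         # (N_T, 3)
    reflection_applied: bool = False
    sign_change: bool = False


def constrain_cm(
    t_unconstrained: np.ndarray,
    centroids: np.ndarray,
    d_max: float,
) -> CMResolution:
    """Blend the unconstrained CM toward the centroid.

    One scalar ``α = min(1, d_max / max_t ‖T_UC − c‖)`` per trial, then
    ``T_C = (1−α) c + α T_UC``, which bounds ‖T_C − c‖ by d_max at every
    step.
    """
    if d_max <= 0:
        raise InvalidInputError("d_max must be positive")
    t_uc = np.asarray(t_unconstrained, dtype=float)
    c = np.asarray(centroids, dtype=float)
    if t_uc.shape != c.shape:
        raise InvalidInputError("series lengths differ")
    dist = np.linalg.norm(t_uc - c, axis=1)
    max_dist = float(dist.max()) if dist.size else 0.0
    alpha = 1.0 if max_dist <= d_max else d_max / max_dist
    t_c = (1.0 - alpha) * c + alpha * t_uc
    return CMResolution(alpha, t_uc, t_c, None, None, c)


def resolve_cm_sign(cm: CMResolution, e_f1: np.ndarray, zero_tol: float = 1e-12) -> CMResolution:
    """Decide whether to reflect the constrained CM about the centroid.

    ΔT(t) is the projection of T_C − c onto the first denoised eigenvector.
    All-negative ΔT keeps T_C; all-positive reflects (T_final = 2c − T_C);
    a genuine sign change is resolved by majority rule on ∫ΔT dt and
    flagged.  Samples with |ΔT| ≤ zero_tol are treated as zero.
    """
    e = np.asarray(e_f1, dtype=float)
    delta = np.einsum("ti,ti->t", cm.t_constrained - cm.centroids, e)
    signif = np.abs(delta) > zero_tol
    has_pos = bool(np.any(delta[signif] > 0))
    has_neg = bool(np.any(delta[signif] < 0))
    if has_pos and has_neg:
        reflect = bool(np.trapezoid(delta) > 0)
        sign_change = True
    elif has_pos:
        reflect, sign_change = True, False
    else:
        reflect, sign_change = False, False
    t_final = 2.0 * cm.centroids - cm.t_constrained if reflect else cm.t_constrained.copy()
    cm.t_final = t_final
    cm.delta_t = delta
    cm.reflection_applied = reflect
    cm.sign_change = sign_change
    return cm


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PctPtDiagnostics:
    denoise_converged: np.ndarray  # (N_T,) bool
    denoise_iterations: np.ndarray
    denoise_final_s: np.ndarray
    step_failed: np.ndarray        # (N_T,) bool (denoise failure or degenerate)
    reasons: list[str]
    valid: bool = True


def pctpt_pose(
    calibration: np.ndarray,
    observed: MarkerTrajectorySet,
    config: PctPtConfig | None = None,
) -> tuple[PoseSeries, MassDistribution, CMResolution, PctPtDiagnostics]:
    """Run the full PCT-PT pipeline on a trial.

    λ₀ and the reference eigenvector basis come from the static calibration
    cluster (unit masses, tensor about the cluster centroid).  The
    orientation is the mean-centred proper-rotation least-squares fit, so it
    coincides exactly with the SVD-LS orientation; the translation maps the
    calibration centroid onto the final CM estimate.
    """
    config = config or PctPtConfig()
    cal = np.asarray(calibration, dtype=float)
    if cal.shape[0] < 4:
        raise InvalidInputError("PCT-PT requires at least 4 markers")
    cal_cm = cal.mean(axis=0)
    cal_eig = eigendecompose(
        inertia_tensor(cal - cal_cm), degeneracy_tol=config.degeneracy_tol
    )
    lam0 = cal_eig.eigenvalues

    n_t = observed.n_samples
    n = observed.n_markers
    tensors = np.empty((n_t, 3, 3))
    e_f1 = np.empty((n_t, 3))
    centroids = np.empty((n_t, 3))
    conv = np.zeros(n_t, dtype=bool)
    iters = np.zeros(n_t, dtype=int)
    final_s = np.ones(n_t)
    failed = np.zeros(n_t, dtype=bool)
    reasons = [""] * n_t

    reference = cal_eig
    for i in range(n_t):
        p = observed.positions[i]
        c = centroid(p)
        centroids[i] = c
        raw = inertia_tensor(p - c)
        try:
            result = denoise_inertia(raw, lam0, config, reference=reference)
            tensors[i] = result.tensor.matrix
            e_f1[i] = result.eigenvectors[:, 0]
            conv[i] = result.converged
            iters[i] = result.iterations
            final_s[i] = result.final_s
            if not result.converged:
                failed[i] = True
                reasons[i] = result.reason
            else:
                reference = EigenDecomposition(result.eigenvalues, result.eigenvectors)
        except DegenerateSpectrumError as exc:
            tensors[i] = raw.matrix
            e_f1[i] = reference.eigenvectors[:, 0]
            failed[i] = True
            reasons[i] = f"degenerate: {exc}"

    # the denoised tensors are centroidal, so the mass-recovery system uses
    # the same centred coordinates
    centred = observed.positions - centroids[:, None, :]
    mass = recover_masses(tensors, centred)
    t_uc = np.stack([weighted_cm(observed.positions[i], mass.masses) for i in range(n_t)])
    cm = constrain_cm(t_uc, centroids, config.d_max)
    cm = resolve_cm_sign(cm, e_f1, config.zero_tol)

    rot = np.empty((n_t, 3, 3))
    trans = np.empty((n_t, 3))
    rms = np.empty(n_t)
    for i in range(n_t):
        r, _, rms_i = kabsch(cal, observed.positions[i])
        rot[i] = r
        trans[i] = cm.t_final[i] - r @ cal_cm
        rms[i] = rms_i

    valid_steps = ~failed
    poses = PoseSeries("PCT-PT", rot, trans, rms, valid=valid_steps)
    diagnostics = PctPtDiagnostics(
        denoise_converged=conv,
        denoise_iterations=iters,
        denoise_final_s=final_s,
        step_failed=failed,
        reasons=reasons,
        valid=bool(np.all(valid_steps)) and mass.converged,
    )
    return poses, mass, cm, diagnostics
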