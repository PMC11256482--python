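"""Jacobian-determinant maps from displacement fields — the DBM core.

For a deformation Phi(x) = x + u(x), J(x) = det(I + grad u(x)) quantifies the
local volume ratio realised by the mapping: J > 1 is local expansion of the
subject relative to the template, J < 1 local contraction. Analysis happens
on the natural-log scale (log J = 0 at identity; additive under composition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imageio import DisplacementField, Volume

LOG_CLAMP = 1e-6


@dataclass
class JacobianMap:
    """log-Jacobian volume plus its companion raw determinant map."""

    log_jacobian: Volume
    determinant: Volume
    n_nonpositive: int = 0
    n_clamped: int = 0


def jacobian_determinant(field: DisplacementField) -> Volume:
    """det(I + grad u) with spacing-aware central differences in world mm.

    Gradients are taken in voxel-index space and mapped through the inverse
    of the affine's linear block, so oblique orientations are handled; central
    differences interior, one-sided at boundary faces (numpy.gradient).
    """
    u = np.asarray(field.data, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement field contains non-finite values")
    A_inv = np.linalg.inv(field.affine[:3, :3])
    grad_vox = np.empty(u.shape[:3] + (3, 3))
    for j in range(3):
        gx, gy, gz = np.gradient(u[..., j], axis=(0, 1, 2))
        grad_vox[..., j, 0], grad_vox[..., j, 1], grad_vox[..., j, 2] = gx, gy, gz
    # du_j/dx_world = du_j/d(index) . d(index)/dx_world
    grad_world = grad_vox @ A_inv
    det = np.linalg.det(np.eye(3) + grad_world)
    return Volume(data=det, affine=field.affine.copy(), units="arbitrary")


def log_jacobian(detmap: Volume, mask: np.ndarray | None = None) -> JacobianMap:
    """Natural log of the determinant map, clamped below at 1e-6.

    log J > 0 marks local expansion, log J < 0 contraction. Non-positive and
    clamped voxel counts are reported, never silently discarded.
    """
    det = np.asarray(detmap.data, dtype=float)
    n_nonpos = int((det <= 0).sum())
    clamped = np.clip(det, LOG_CLAMP, None)
    n_clamped = int((det < LOG_CLAMP).sum())
    logj = np.log(clamped)
    if mask is not None:
        logj = np.where(mask, logj, 0.0)
    return JacobianMap(
        log_jacobian=Volume(data=logj, affine=detmap.affine.copy(), units="log-ratio"),
        determinant=detmap,
        n_nonpositive=n_nonpos,
        n_clamped=n_clamped,
    )


def log_jacobian_of_field(field: DisplacementField, mask: np.ndarray | None = None) -> JacobianMap:
    """Convenience composition: displacement field -> log-Jacobian map."""
    return log_jacobian(jacobian_determinant(field), mask=mask)
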