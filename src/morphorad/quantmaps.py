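"""Microstructural parameter maps: DTI scalars and steady-state CBV.

The diffusion tensor is fitted voxel-wise by log-linear least squares on
ln S = ln S0 - b g^T D g (6 unique tensor elements + intercept); MD, AD and RD
are eigenvalue summaries exported in um^2/s. Cerebral blood volume follows the
steady-state susceptibility-contrast model: DR2* = ln(S_pre/S_post)/TE and
CBV(%) = 100 * (3/4pi) * DR2* / (gamma * dchi * B0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imageio import Volume
from .phantom import ContrastProtocol, DWIProtocol

MM2_TO_UM2 = 1.0e6  # mm^2/s -> um^2/s


@dataclass
class TensorMap:
    """Voxel-wise symmetric diffusion tensors (mm^2/s) with eigendecomposition.

    Eigenvalues are sorted descending (lambda1 >= lambda2 >= lambda3).
    Negative eigenvalues are flagged, and a clamped copy is kept separately so
    stored maps preserve the raw fit.
    """

    tensors: np.ndarray            # (X, Y, Z, 3, 3)
    eigenvalues: np.ndarray        # (X, Y, Z, 3), descending
    eigenvectors: np.ndarray       # (X, Y, Z, 3, 3), columns match eigenvalues
    s0: np.ndarray                 # fitted S0
    affine: np.ndarray
    mask: np.ndarray
    n_negative_eig: int = 0
    n_excluded: int = 0

    @property
    def eigenvalues_clamped(self) -> np.ndarray:
        return np.clip(self.eigenvalues, 0.0, None)

    @property
    def principal_axis(self) -> np.ndarray:
        return self.eigenvectors[..., :, 0]


@dataclass
class CBVMap:
    """Cerebral blood volume in % (ml blood / 100 ml tissue) plus its DR2* map."""

    cbv: Volume
    delta_r2star: Volume
    n_negative: int = 0


def _design_matrix(protocol: DWIProtocol) -> np.ndarray:
    b, g = protocol.bvals, protocol.bvecs
    return np.stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2.0 * b * g[:, 0] * g[:, 1],
            -2.0 * b * g[:, 0] * g[:, 2],
            -2.0 * b * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )


def fit_dti(dwi: Volume, protocol: DWIProtocol, mask: np.ndarray | None = None) -> TensorMap:
    """Log-linear least-squares tensor fit per masked voxel (deterministic).

    Voxels with any non-positive signal are excluded from the fit and
    flagged; the design must be full rank (>= 6 distinct directions + b0).
    """
    data = np.asarray(dwi.data, dtype=float)
    if data.ndim != 4 or data.shape[-1] != protocol.n_measurements:
        raise ValueError("dwi must be 4D with one volume per protocol measurement")
    X = _design_matrix(protocol)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient design: need >= 6 non-collinear directions plus b0")
    shape3 = data.shape[:3]
    if mask is None:
        mask = np.ones(shape3, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    fit_mask = mask & np.all(data > 0, axis=-1)
    n_excluded = int(mask.sum() - fit_mask.sum())

    pinv = np.linalg.pinv(X)
    logs = np.log(data[fit_mask])               # (n_vox, n_meas)
    coeffs = logs @ pinv.T                      # (n_vox, 7)

    tensors = np.zeros(shape3 + (3, 3))
    dxx, dyy, dzz, dxy, dxz, dyz = (coeffs[:, i] for i in range(1, 7))
    T = np.zeros(coeffs.shape[0:1] + (3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = dxx, dyy, dzz
    T[:, 0, 1] = T[:, 1, 0] = dxy
    T[:, 0, 2] = T[:, 2, 0] = dxz
    T[:, 1, 2] = T[:, 2, 1] = dyz
    tensors[fit_mask] = T

    s0 = np.zeros(shape3)
    s0[fit_mask] = np.exp(coeffs[:, 0])

    evals = np.zeros(shape3 + (3,))
    evecs = np.zeros(shape3 + (3, 3))
    w, v = np.linalg.eigh(T)                    # ascending
    order = np.argsort(w, axis=-1)[:, ::-1]
    w_sorted = np.take_along_axis(w, order, axis=-1)
    v_sorted = np.take_along_axis(v, order[:, None, :], axis=-1)
    evals[fit_mask] = w_sorted
    evecs[fit_mask] = v_sorted

    return TensorMap(
        tensors=tensors, eigenvalues=evals, eigenvectors=evecs, s0=s0,
        affine=dwi.affine.copy(), mask=fit_mask,
        n_negative_eig=int((w_sorted < 0).any(axis=-1).sum()), n_excluded=n_excluded,
    )


def dti_scalars(tensors: TensorMap) -> tuple[Volume, Volume, Volume]:
    """(MD, AD, RD) volumes in um^2/s.

    MD = (l1+l2+l3)/3, AD = l1, RD = (l2+l3)/2 on the descending eigenvalues;
    the 1e6 factor converts the tensor's mm^2/s to the reporting scale
    (0.7e-3 mm^2/s -> 700 um^2/s).
    """
    ev = tensors.eigenvalues
    md = ev.mean(axis=-1) * MM2_TO_UM2
    ad = ev[..., 0] * MM2_TO_UM2
    rd = ev[..., 1:].mean(axis=-1) * MM2_TO_UM2
    mk = lambda d: Volume(data=d, affine=tensors.affine.copy(), units="um^2/s")
    return mk(md), mk(ad), mk(rd)


def delta_r2star(pre: Volume, post: Volume, te: float) -> tuple[Volume, int]:
    """DR2* = ln(S_pre / S_post) / TE in s^-1.

    Voxels with non-positive signal in either image are set to 0 and counted;
    voxels where S_post >= S_pre yield DR2* <= 0 and are counted as flagged
    (returned as the second element) but kept in the map.
    """
    if te <= 0:
        raise ValueError("te must be > 0")
    if not pre.same_geometry(post):
        raise ValueError("pre and post geometries differ")
    s_pre = np.asarray(pre.data, dtype=float)
    s_post = np.asarray(post.data, dtype=float)
    valid = (s_pre > 0) & (s_post > 0)
    dr2s = np.zeros(s_pre.shape)
    dr2s[valid] = np.log(s_pre[valid] / s_post[valid]) / te
    n_flagged = int((dr2s[valid] <= 0).sum())
    return Volume(data=dr2s, affine=pre.affine.copy(), units="s^-1"), n_flagged


def cbv_map(dr2s: Volume, protocol: ContrastProtocol | None = None,
            gamma_dchi_b0: float | None = None) -> CBVMap:
    """CBV(%) = 100 * (3/4pi) * DR2* / (gamma * dchi * B0).

    Negative-CBV voxels (DR2* < 0, e.g. from noise) are flagged, not clipped.
    """
    if gamma_dchi_b0 is None:
        if protocol is None:
            raise ValueError("provide a ContrastProtocol or gamma_dchi_b0")
        gamma_dchi_b0 = protocol.gamma_dchi_b0
    if gamma_dchi_b0 == 0:
        raise ValueError("gamma * dchi * B0 must be non-zero")
    cbv = 100.0 * (3.0 / (4.0 * np.pi)) * np.asarray(dr2s.data, dtype=float) / gamma_dchi_b0
    return CBVMap(
        cbv=Volume(data=cbv, affine=dr2s.affine.copy(), units="%"),
        delta_r2star=dr2s,
        n_negative=int((cbv < 0).sum()),
    )
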