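"""Synthetic rodent-brain phantom cohorts with analytic ground truth.

The generator emulates a two-group (control / irradiated) longitudinal MRI
study: T2w anatomy, 30-direction DWI, and pre/post-contrast T2* pairs, all
written as NIfTI-1. Focal volume changes are planted as Gaussian-radial
deformations whose Jacobian determinant is available in closed form, so the
whole morphometry pipeline can be validated against exact ground truth.

Conventions
-----------
A planted ``volume_ratio`` r is the Jacobian of the template->subject map at
the blob centre — the quantity the registration pipeline is expected to
recover. Subject images are synthesised by pulling the clean phantom back
through the numerically inverted blob field, so the analytic evaluator of the
forward field is the exact ground truth for the recovered deformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imageio import DisplacementField, Volume

# label codes of the phantom tissue classes
BACKGROUND = 0
CORTEX = 1
STRIATUM = 2
CORPUS_CALLOSUM = 3
VENTRICLES = 4

LABEL_NAMES = {
    BACKGROUND: "background",
    CORTEX: "cortex",
    STRIATUM: "striatum",
    CORPUS_CALLOSUM: "corpus_callosum",
    VENTRICLES: "ventricles",
}

# T2w-like mean intensities (arbitrary units): CSF bright, white matter dark
DEFAULT_INTENSITIES = {
    "background": 0.0,
    "cortex": 100.0,
    "striatum": 90.0,
    "corpus_callosum": 70.0,
    "ventricles": 180.0,
}

# geometry fractions of the field of view (world mm), fixed phantom anatomy
_GEOM = {
    "brain_semiaxes": (0.40, 0.40, 0.40),
    "cc_z_center": 0.08,
    "cc_half_thickness": 0.07,
    "cc_semiaxes_xy": (0.30, 0.22),
    "striatum_centers_x": 0.14,
    "striatum_center_z": -0.10,
    "striatum_semiaxes": (0.10, 0.13, 0.11),
    "ventricle_centers_x": 0.07,
    "ventricle_center_z": 0.22,
    "ventricle_semiaxes": (0.06, 0.12, 0.08),
}


@dataclass
class PhantomSpec:
    """Geometry, intensities and degradation parameters of one phantom brain.

    noise_sigma is the Rician noise scale relative to the cortex mean
    intensity; bias_amplitude is the peak deviation of the multiplicative
    bias field from 1.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (0.25, 0.25, 0.5)
    intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    brain_scale: float = 1.0
    noise_sigma: float = 0.03
    bias_amplitude: float = 0.1
    texture_amplitude: float = 0.0
    texture_scale_mm: float = 1.0
    psf_fwhm_mm: float = 0.0  # acquisition point-spread blur applied after warping
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too small to contain the brain geometry (need >= 8 voxels per axis)")
        if self.brain_scale <= 0:
            raise ValueError("degenerate geometry: brain_scale must be > 0")
        if self.brain_scale * max(_GEOM["brain_semiaxes"]) > 0.5:
            raise ValueError("brain geometry does not fit inside the grid")
        missing = set(DEFAULT_INTENSITIES) - set(self.intensities)
        if missing:
            raise ValueError(f"missing intensities for classes: {sorted(missing)}")

    @property
    def fov(self) -> np.ndarray:
        """Field of view in mm per axis."""
        return np.asarray(self.grid_shape, dtype=float) * np.asarray(self.spacing, dtype=float)

    @property
    def affine(self) -> np.ndarray:
        """RAS+ affine with the world origin at the grid centre."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = -(np.asarray(self.grid_shape, dtype=float) - 1) / 2.0 * np.asarray(self.spacing)
        return aff

    @property
    def noise_sigma_abs(self) -> float:
        return self.noise_sigma * self.intensities["cortex"]


@dataclass
class FocalDeformationSpec:
    """A Gaussian-radial focal volume change.

    volume_ratio is the Jacobian determinant at the blob centre: < 1 plants a
    local contraction, > 1 a local expansion.
    """

    center: tuple[float, float, float]
    sigma: float
    volume_ratio: float

    def __post_init__(self) -> None:
        if self.volume_ratio <= 0:
            raise ValueError("volume_ratio must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def amplitude(self) -> float:
        """Radial scale a with u(x) = a (x - c) exp(-|x-c|^2 / 2 sigma^2)."""
        return self.volume_ratio ** (1.0 / 3.0) - 1.0


@dataclass
class DWIProtocol:
    """b-values (s/mm^2) and unit gradient directions, FSL bval/bvec layout."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (N, 3) unit vectors; arbitrary for b=0
    s0: float = 100.0
    te: float = 0.037
    tr: float = 2.2

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (N, 3) matching bvals")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if nz.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gradient directions must be unit-norm")
        if self.n_measurements < 7:
            raise ValueError("tensor fit needs >= 7 measurements (>= 6 directions + b0)")

    @property
    def n_measurements(self) -> int:
        return int(self.bvals.size)


def fibonacci_directions(n: int = 30) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    vecs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


def default_dwi_protocol(n_b0: int = 5, n_dirs: int = 30, b: float = 1000.0, s0: float = 100.0) -> DWIProtocol:
    """30 directions, two b-values (0 and 1000 s/mm^2), five b0 images."""
    dirs = fibonacci_directions(n_dirs)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, b)])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), dirs])
    return DWIProtocol(bvals=bvals, bvecs=bvecs, s0=s0)


@dataclass
class ContrastProtocol:
    """Steady-state susceptibility-contrast acquisition constants.

    te: gradient-echo time (s). b0: main field (T). gamma: proton gyromagnetic
    ratio (rad s^-1 T^-1). delta_chi: susceptibility increase from the
    intravascular contrast agent (nonrationalized units); the product
    gamma * delta_chi * b0 is the single calibration constant of the CBV map.
    """

    te: float = 0.013
    b0: float = 7.0
    gamma: float = 2.675e8
    delta_chi: float = 1.0e-7

    def __post_init__(self) -> None:
        if self.te <= 0 or self.b0 <= 0 or self.gamma <= 0:
            raise ValueError("te, gamma and b0 must be > 0")
        if self.delta_chi <= 0:
            raise ValueError("delta_chi must be > 0")

    @property
    def gamma_dchi_b0(self) -> float:
        return self.gamma * self.delta_chi * self.b0


# ---------------------------------------------------------------------------
# phantom anatomy


def make_phantom(spec: PhantomSpec) -> tuple[Volume, Volume]:
    """Build the noise-free intensity volume and its ground-truth label map."""
    aff = spec.affine
    shape = tuple(spec.grid_shape)
    idx = np.indices(shape, dtype=float)
    xyz = np.moveaxis(idx, 0, -1) @ aff[:3, :3].T + aff[:3, 3]
    fov = spec.fov
    s = spec.brain_scale

    def ellipsoid(center_frac, semi_frac):
        c = np.asarray(center_frac) * fov
        ax = np.asarray(semi_frac) * fov * s
        d = (xyz - c) / ax
        return np.einsum("...k,...k->...", d, d) <= 1.0

    labels = np.zeros(shape, dtype=np.int32)
    brain = ellipsoid((0, 0, 0), _GEOM["brain_semiaxes"])
    labels[brain] = CORTEX

    sx = _GEOM["striatum_centers_x"]
    sz = _GEOM["striatum_center_z"]
    for side in (-1, 1):
        labels[ellipsoid((side * sx, 0, sz), _GEOM["striatum_semiaxes"]) & brain] = STRIATUM

    ax, by = (np.asarray(_GEOM["cc_semiaxes_xy"]) * fov[:2] * s)
    zc = _GEOM["cc_z_center"] * fov[2]
    zh = _GEOM["cc_half_thickness"] * fov[2] * s
    cc = (np.abs(xyz[..., 2] - zc) <= zh) & ((xyz[..., 0] / ax) ** 2 + (xyz[..., 1] / by) ** 2 <= 1.0) & brain
    labels[cc] = CORPUS_CALLOSUM

    vx = _GEOM["ventricle_centers_x"]
    vz = _GEOM["ventricle_center_z"]
    for side in (-1, 1):
        labels[ellipsoid((side * vx, 0, vz), _GEOM["ventricle_semiaxes"]) & brain] = VENTRICLES

    data = np.zeros(shape, dtype=float)
    for code, name in LABEL_NAMES.items():
        data[labels == code] = spec.intensities[name]

    if spec.texture_amplitude > 0:
        # fixed intra-tissue texture: part of the anatomy, identical for every
        # subject drawn from this spec (it is what registration locks onto)
        trng = np.random.default_rng(7654321)
        tex = trng.standard_normal(shape)
        sigma_vox = spec.texture_scale_mm / np.asarray(spec.spacing)
        tex = ndimage.gaussian_filter(tex, sigma_vox)
        tex /= tex.std()
        data *= 1.0 + spec.texture_amplitude * tex

    vol = Volume(data=data, affine=aff)
    lab = Volume(data=labels, affine=aff, units="label")
    return vol, lab


def write_label_names(path: str | Path) -> Path:
    """Write the phantom atlas naming table (label_id, name, area_group)."""
    rows = [
        {"label_id": code, "name": name, "area_group": "brain" if code else "background"}
        for code, name in LABEL_NAMES.items()
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# deformations


def make_deformation(specs: list[FocalDeformationSpec], reference: Volume):
    """Sum-of-Gaussian-blobs displacement field with its analytic Jacobian.

    Returns (field, analytic_jacobian) where analytic_jacobian maps world
    coordinates (..., 3) to det(I + grad u) evaluated in closed form. At each
    blob centre the determinant equals that blob's volume_ratio exactly
    (when blobs do not interact).
    """
    for i, a in enumerate(specs):
        for b in specs[i + 1:]:
            dist = np.linalg.norm(np.asarray(a.center) - np.asarray(b.center))
            if dist < 3.0 * (a.sigma + b.sigma):
                warnings.warn(
                    f"focal deformations at {a.center} and {b.center} overlap "
                    f"(distance {dist:.2f} mm < 3*(sigma_i+sigma_j)); centre Jacobians are no longer exact",
                    stacklevel=2,
                )

    def displacement(coords: np.ndarray) -> np.ndarray:
        u = np.zeros_like(coords)
        for sp in specs:
            d = coords - np.asarray(sp.center, dtype=float)
            g = np.exp(-np.einsum("...k,...k->...", d, d) / (2.0 * sp.sigma ** 2))
            u += sp.amplitude * g[..., None] * d
        return u

    def analytic_jacobian(coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        grad = np.zeros(coords.shape[:-1] + (3, 3))
        eye = np.eye(3)
        for sp in specs:
            d = coords - np.asarray(sp.center, dtype=float)
            g = np.exp(-np.einsum("...k,...k->...", d, d) / (2.0 * sp.sigma ** 2))
            outer = np.einsum("...j,...k->...jk", d, d) / sp.sigma ** 2
            grad += sp.amplitude * g[..., None, None] * (eye - outer)
        return np.linalg.det(eye + grad)

    coords = reference.world_grid()
    fld = DisplacementField(data=displacement(coords), affine=reference.affine.copy())
    fld.displacement_fn = displacement  # analytic closure, used for exact composition
    return fld, analytic_jacobian


def invert_field(fieldobj: DisplacementField, n_iter: int = 30) -> DisplacementField:
    """Fixed-point inversion: v(y) = -u(y + v(y)); exact when the closure is attached."""
    ref = fieldobj.as_volume()
    coords = ref.world_grid()
    fn = getattr(fieldobj, "displacement_fn", None)
    if fn is None:
        fn = lambda pts: _interpolate_field(fieldobj, pts)
    v = np.zeros_like(coords)
    for _ in range(n_iter):
        v = -fn(coords + v)
    return DisplacementField(data=v, affine=fieldobj.affine.copy(), direction="inverse")


def _interpolate_field(fieldobj: DisplacementField, pts: np.ndarray) -> np.ndarray:
    vol = fieldobj.as_volume()
    inv = np.linalg.inv(fieldobj.affine)
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    stacked = [
        ndimage.map_coordinates(fieldobj.data[..., k], np.moveaxis(vox, -1, 0), order=1, mode="nearest")
        for k in range(3)
    ]
    return np.stack(stacked, axis=-1)


def resample_through_map(volume: Volume, coords_world: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Sample `volume` at arbitrary world coordinates (linear by default)."""
    inv = np.linalg.inv(volume.affine)
    vox = coords_world @ inv[:3, :3].T + inv[:3, 3]
    return ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float), np.moveaxis(vox, -1, 0), order=order, mode="constant", cval=cval
    )


def make_bias_field(reference: Volume, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias: 1 + amplitude * random quadratic, peak-normalised."""
    if amplitude == 0:
        return np.ones(reference.shape3)
    coords = reference.world_grid()
    half = np.asarray(reference.shape3) * reference.spacing / 2.0
    xn = coords / half  # normalised to roughly [-1, 1]
    terms = [
        np.ones(reference.shape3),
        xn[..., 0], xn[..., 1], xn[..., 2],
        xn[..., 0] ** 2, xn[..., 1] ** 2, xn[..., 2] ** 2,
        xn[..., 0] * xn[..., 1], xn[..., 0] * xn[..., 2], xn[..., 1] * xn[..., 2],
    ]
    w = rng.standard_normal(len(terms))
    w[0] = 0.0
    f = sum(wi * t for wi, t in zip(w, terms))
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return 1.0 + amplitude * f


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((s + n1)^2 + n2^2), n1,n2 ~ N(0, sigma)."""
    if sigma <= 0:
        return np.asarray(signal, dtype=float)
    n1 = rng.normal(0.0, sigma, size=np.shape(signal))
    n2 = rng.normal(0.0, sigma, size=np.shape(signal))
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


def warp_and_degrade(
    volume: Volume,
    fieldobj: DisplacementField | None,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    bias: np.ndarray | None = None,
) -> Volume:
    """Resample through Phi(x)=x+u(x) (linear), apply bias, add Rician noise."""
    if fieldobj is not None and not volume.same_geometry(fieldobj):
        raise ValueError("field and volume geometries differ")
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    if fieldobj is None:
        out = np.asarray(volume.data, dtype=float).copy()
    else:
        coords = volume.world_grid() + fieldobj.data
        out = resample_through_map(volume, coords, order=1)
    if spec.psf_fwhm_mm > 0:
        # acquisition PSF acts in the scanner frame, i.e. after the anatomy
        # is placed: it damps the pose-dependent rendering of sharp edges
        out = ndimage.gaussian_filter(out, (spec.psf_fwhm_mm / 2.355) / np.asarray(volume.spacing))
    if bias is None:
        bias = make_bias_field(volume, spec.bias_amplitude, rng)
    out = out * bias
    out = add_rician_noise(out, spec.noise_sigma_abs, rng)
    return volume.copy_with(out)


# ---------------------------------------------------------------------------
# signal models


def simulate_dwi(
    tensors: np.ndarray,
    protocol: DWIProtocol,
    affine: np.ndarray,
    s0: np.ndarray | float | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Volume:
    """Monoexponential tensor signal S(g, b) = s0 exp(-b g^T D g) per voxel.

    tensors: (X, Y, Z, 3, 3) symmetric positive semi-definite, in mm^2/s.
    """
    tensors = np.asarray(tensors, dtype=float)
    if tensors.ndim != 5 or tensors.shape[-2:] != (3, 3):
        raise ValueError("tensors must have shape (X, Y, Z, 3, 3)")
    if not np.allclose(tensors, np.swapaxes(tensors, -1, -2), atol=1e-12):
        raise ValueError("tensors must be symmetric")
    s0_arr = np.full(tensors.shape[:3], protocol.s0) if s0 is None else np.broadcast_to(np.asarray(s0, dtype=float), tensors.shape[:3])
    # b * g^T D g for all measurements at once
    gdg = np.einsum("nj,...jk,nk->...n", protocol.bvecs, tensors, protocol.bvecs)
    signal = s0_arr[..., None] * np.exp(-protocol.bvals * gdg)
    if noise_sigma > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        signal = add_rician_noise(signal, noise_sigma, rng)
    return Volume(data=signal, affine=affine)


def simulate_t2star(
    cbv: Volume,
    protocol: ContrastProtocol,
    pre_signal: Volume,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[Volume, Volume]:
    """Pre/post-contrast pair: DR2* = (CBV/100)(4pi/3) gamma dchi B0; post = pre exp(-DR2* TE)."""
    if np.any(np.asarray(cbv.data) < 0):
        raise ValueError("cbv must be >= 0 (in %)")
    if not cbv.same_geometry(pre_signal):
        raise ValueError("cbv and pre_signal geometries differ")
    dr2s = (np.asarray(cbv.data, dtype=float) / 100.0) * (4.0 * np.pi / 3.0) * protocol.gamma_dchi_b0
    pre = np.asarray(pre_signal.data, dtype=float)
    post = pre * np.exp(-dr2s * protocol.te)
    if noise_sigma > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        pre = add_rician_noise(pre, noise_sigma, rng)
        post = add_rician_noise(post, noise_sigma, rng)
    return pre_signal.copy_with(pre), pre_signal.copy_with(post)


# ---------------------------------------------------------------------------
# tissue parameter fields

# baseline diffusion eigenvalues per tissue (mm^2/s): CC anisotropic along x
TISSUE_EIGENVALUES = {
    "background": (0.0, 0.0, 0.0),
    "cortex": (8.207e-4, 8.207e-4, 8.207e-4),
    "striatum": (7.5e-4, 7.5e-4, 7.5e-4),
    "corpus_callosum": (1.5e-3, 3.937e-4, 3.937e-4),
    "ventricles": (2.4e-3, 2.4e-3, 2.4e-3),
}

# baseline cerebral blood volume per tissue (%)
TISSUE_CBV = {
    "background": 0.0,
    "cortex": 6.83,
    "striatum": 5.0,
    "corpus_callosum": 3.20,
    "ventricles": 0.0,
}


def tissue_tensor_field(labels: Volume, md_scale: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel diffusion tensors from the label map; CC principal axis is +x.

    md_scale optionally multiplies all eigenvalues voxel-wise (planted MD change).
    """
    lab = np.asarray(labels.data)
    tensors = np.zeros(lab.shape + (3, 3))
    for code, name in LABEL_NAMES.items():
        ev = TISSUE_EIGENVALUES[name]
        tensors[lab == code] = np.diag(ev)
    if md_scale is not None:
        tensors = tensors * np.asarray(md_scale)[..., None, None]
    return tensors


def tissue_cbv_field(labels: Volume, cbv_scale: np.ndarray | None = None) -> Volume:
    lab = np.asarray(labels.data)
    cbv = np.zeros(lab.shape)
    for code, name in LABEL_NAMES.items():
        cbv[lab == code] = TISSUE_CBV[name]
    if cbv_scale is not None:
        cbv = cbv * np.asarray(cbv_scale)
    return Volume(data=cbv, affine=labels.affine.copy(), units="%")
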