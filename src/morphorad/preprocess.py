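"""Brain masking and intensity-inhomogeneity correction.

The mask is deterministic (Otsu threshold, largest 26-connected component,
morphological closing, hole filling); a user-supplied mask can override it.
Bias correction divides out a low-order polynomial fitted to log-intensities
inside the mask and preserves the masked median intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .imageio import Volume

logger = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Mask:
    volume: Volume  # binary data
    provenance: str = "auto"

    def __post_init__(self) -> None:
        self.volume.data = np.asarray(self.volume.data).astype(bool)
        if not self.volume.data.any():
            raise ValueError("mask is empty")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def brain_mask(volume: Volume, closing_radius: int = 2) -> Mask:
    """Otsu threshold -> largest 26-connected component -> closing -> fill holes."""
    data = np.asarray(volume.data, dtype=float)
    if np.ptp(data) == 0:
        raise ValueError("no threshold separates classes: image is constant")
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise ValueError("no threshold separates classes: empty foreground")
    lab, n = ndimage.label(fg, structure=_CONN26)
    largest = np.argmax(ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))) + 1
    fg = lab == largest
    fg = ndimage.binary_closing(fg, structure=ball(closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    # closing can merge satellites back in; keep the single largest component
    lab, n = ndimage.label(fg, structure=_CONN26)
    if n > 1:
        largest = np.argmax(ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))) + 1
        fg = lab == largest
    return Mask(volume=volume.copy_with(fg.astype(np.uint8), units="label"), provenance="auto")


def whole_brain_volume(mask: Mask | Volume) -> float:
    """Foreground voxel count times voxel volume, in mm^3."""
    vol = mask.volume if isinstance(mask, Mask) else mask
    return float(np.count_nonzero(vol.data)) * vol.voxel_volume


def _poly_design(volume: Volume, where: np.ndarray, order: int = 2) -> np.ndarray:
    coords = volume.world_grid()[where]
    half = np.asarray(volume.shape3) * volume.spacing / 2.0
    x, y, z = (coords / half).T
    cols = [np.ones_like(x), x, y, z]
    if order >= 2:
        cols += [x * x, y * y, z * z, x * y, x * z, y * z]
    return np.stack(cols, axis=1)


def _kmeans_1d(values: np.ndarray, k: int, n_iter: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D k-means with quantile initialisation."""
    centers = np.quantile(values, (np.arange(k) + 0.5) / k)
    for _ in range(n_iter):
        assign = np.abs(values[:, None] - centers[None, :]).argmin(axis=1)
        for c in range(k):
            sel = assign == c
            if sel.any():
                centers[c] = values[sel].mean()
    return centers, np.abs(values[:, None] - centers[None, :]).argmin(axis=1)


def bias_correct(volume: Volume, mask: Mask, order: int = 2, n_classes: int = 4,
                 n_iter: int = 4) -> Volume:
    """Divide out a smooth multiplicative bias estimated inside the mask.

    The log-intensity of each masked voxel is modelled as a piecewise-constant
    tissue term (1-D k-means classes) plus an order-2 (10-coefficient)
    polynomial bias; the polynomial is fitted by least squares to the residual
    from the tissue model and divided out, so an image without inhomogeneity
    passes through unchanged. The masked median intensity is preserved.
    Non-positive voxels inside the mask are clipped to the smallest positive
    masked value (with a warning in the log) before taking logs.
    """
    data = np.asarray(volume.data, dtype=float).copy()
    m = mask.data
    vals = data[m]
    nonpos = vals <= 0
    if nonpos.any():
        floor = vals[~nonpos].min() if (~nonpos).any() else 1e-6
        logger.warning("bias_correct: clipping %d non-positive masked voxels to %.3g", int(nonpos.sum()), floor)
        vals = np.where(nonpos, floor, vals)
        data[m] = vals
    log_vals = np.log(vals)
    design = _poly_design(volume, m, order=order)

    def alternate(log_bias0: np.ndarray) -> tuple[np.ndarray, float]:
        lb = log_bias0
        c = np.zeros(design.shape[1])
        for _ in range(n_iter):
            centers, assign = _kmeans_1d(log_vals - lb, n_classes)
            residual = log_vals - centers[assign]
            c, *_ = np.linalg.lstsq(design, residual, rcond=None)
            lb = design @ c
            lb -= lb.mean()
        centers, assign = _kmeans_1d(log_vals - lb, n_classes)
        score = float(np.sqrt(np.mean((log_vals - lb - centers[assign]) ** 2)))
        return c, score

    # the alternation (classify tissues <-> fit bias) has two basins: classes
    # can absorb a strong bias, or a plain first fit can seed clean classes.
    # Run both initialisations and keep the lower within-class residual.
    plain, *_ = np.linalg.lstsq(design, log_vals - log_vals.mean(), rcond=None)
    lb_plain = design @ plain
    candidates = [alternate(np.zeros_like(log_vals)), alternate(lb_plain - lb_plain.mean())]
    coef, _ = min(candidates, key=lambda cs: cs[1])
    full = _poly_design(volume, np.ones(volume.shape3, dtype=bool), order=order)
    log_bias = (full @ coef).reshape(volume.shape3)
    log_bias -= log_bias[m].mean()
    corrected = data / np.exp(log_bias)
    med_in, med_out = np.median(data[m]), np.median(corrected[m])
    if med_out > 0:
        corrected *= med_in / med_out
    return volume.copy_with(corrected)
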