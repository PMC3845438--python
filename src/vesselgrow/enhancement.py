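"""Multiscale Hessian-based vessel enhancement for 2D images and 3D volumes.

The per-scale filter rewards bright tubular structure: eigenvalues of the
Gaussian-smoothed Hessian are ordered by magnitude, geometric ratios measure
blobness/anisotropy, and a structureness term suppresses responses in flat
noise.  Responses across scales are fused by a pointwise maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError

__all__ = [
    "HessianField",
    "VesselnessParams",
    "gaussian_hessian",
    "blobness_ratio_2d",
    "blobness_ratio_3d",
    "anisotropy_ratio_3d",
    "vesselness_2d",
    "vesselness_3d",
    "multiscale_enhance",
]

DEFAULT_SCALES = (1.0, 3.0, 5.0, 7.0)


@dataclass
class HessianField:
    """Scale-normalized Hessian and its |.|-ordered eigenvalues.

    ``eigenvalues[..., i]`` is the i-th eigenvalue sorted by increasing
    absolute value, so ``|lam1| <= |lam2| (<= |lam3|)``.  ``structureness``
    is the Frobenius norm of the Hessian at each pixel.
    """

    sigma: float
    hessian: np.ndarray  # (..., d, d)
    eigenvalues: np.ndarray  # (..., d)
    structureness: np.ndarray  # (...)

    @property
    def ndim(self) -> int:
        return self.eigenvalues.shape[-1]


@dataclass
class VesselnessParams:
    """Sensitivity parameters and the scale set for the multiscale filter."""

    alpha: float = 0.5
    beta: float = 0.5
    c: float | None = None  # None: half the max Frobenius norm at each scale
    scales: tuple[float, ...] = DEFAULT_SCALES
    # "frobenius": structureness term uses the per-pixel Frobenius norm S.
    # "sigma": literal printed form exp term uses the scale value instead.
    structureness_mode: str = "frobenius"

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise InvalidParameterError("alpha and beta must be positive")
        if self.c is not None and self.c <= 0:
            raise InvalidParameterError("c must be positive")
        scales = tuple(float(s) for s in self.scales)
        if not scales:
            raise InvalidParameterError("scales must be non-empty")
        if any(s <= 0 for s in scales) or any(
            b <= a for a, b in zip(scales, scales[1:])
        ):
            raise InvalidParameterError("scales must be positive, strictly increasing")
        if self.structureness_mode not in ("frobenius", "sigma"):
            raise InvalidParameterError("structureness_mode must be frobenius|sigma")
        self.scales = scales


def gaussian_hessian(image: np.ndarray, sigma: float) -> HessianField:
    """Second derivatives by Gaussian convolution at scale ``sigma``.

    Derivatives are multiplied by sigma**2 (gamma = 2 normalization) so
    responses are comparable across scales.  Reflect boundary handling.
    """
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive")
    image = np.asarray(image, dtype=float)
    if image.ndim not in (2, 3) or min(image.shape) < 2:
        raise InvalidParameterError("image must be 2D or 3D with >= 2 px per axis")
    d = image.ndim
    H = np.empty(image.shape + (d, d))
    for i in range(d):
        for j in range(i, d):
            order = [0] * d
            order[i] += 1
            order[j] += 1
            der = ndimage.gaussian_filter(image, sigma, order=order, mode="reflect")
            H[..., i, j] = der
            H[..., j, i] = der
    H *= sigma**2
    eigs = _abs_sorted_eigenvalues(H)
    S = np.sqrt(np.sum(H**2, axis=(-2, -1)))
    return HessianField(sigma=float(sigma), hessian=H, eigenvalues=eigs,
                        structureness=S)


def _abs_sorted_eigenvalues(H: np.ndarray) -> np.ndarray:
    d = H.shape[-1]
    if d == 2:
        a = H[..., 0, 0]
        b = H[..., 0, 1]
        c = H[..., 1, 1]
        half_tr = (a + c) / 2.0
        disc = np.sqrt(((a - c) / 2.0) ** 2 + b**2)
        lam = np.stack([half_tr - disc, half_tr + disc], axis=-1)
    else:
        lam = np.linalg.eigvalsh(H)
    order = np.argsort(np.abs(lam), axis=-1, kind="stable")
    return np.take_along_axis(lam, order, axis=-1)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """num/den with 0/0 -> 0 and x/0 (x != 0) capped at a large constant."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast_shapes(num.shape, den.shape), 1e12)
    np.divide(num, den, out=out, where=den != 0)
    out = np.where((den == 0) & (num == 0), 0.0, out)
    return np.minimum(out, 1e12)


def blobness_ratio_2d(lam1, lam2):
    """|lam1| / |lam2|; 0 for an ideal line, 1 for an isotropic blob."""
    return _safe_ratio(np.abs(lam1), np.abs(lam2))


def blobness_ratio_3d(lam1, lam2, lam3):
    """|lam1| / sqrt(|lam2 * lam3|); 0 for an ideal tube, 1 for a blob."""
    return _safe_ratio(np.abs(lam1), np.sqrt(np.abs(np.asarray(lam2, dtype=float)
                                                    * np.asarray(lam3, dtype=float))))


def anisotropy_ratio_3d(lam2, lam3):
    """|lam2| / |lam3| in [0, 1]; close to 1 for tubular structure."""
    return _safe_ratio(np.abs(lam2), np.abs(lam3))


def _structureness_term(field: HessianField, params: VesselnessParams):
    if params.structureness_mode == "sigma":
        S = np.full(field.structureness.shape, field.sigma)
    else:
        S = field.structureness
    c = params.c
    if c is None:
        smax = float(S.max())
        c = smax / 2.0 if smax > 0 else 1.0
    return 1.0 - np.exp(-(S**2) / (2.0 * c**2))


def vesselness_2d(field: HessianField, params: VesselnessParams | None = None
                  ) -> np.ndarray:
    """Per-pixel tubularity score in [0, 1] for a 2D Hessian field."""
    params = params or VesselnessParams()
    if field.ndim != 2:
        raise InvalidParameterError("vesselness_2d needs a 2D HessianField")
    lam1 = field.eigenvalues[..., 0]
    lam2 = field.eigenvalues[..., 1]
    rb = blobness_ratio_2d(lam1, lam2)
    v = np.exp(-(rb**2) / (2.0 * params.beta**2)) * _structureness_term(field, params)
    return np.where(lam2 > 0, 0.0, v)


def vesselness_3d(field: HessianField, params: VesselnessParams | None = None
                  ) -> np.ndarray:
    """Per-voxel tubularity score in [0, 1] for a 3D Hessian field."""
    params = params or VesselnessParams()
    if field.ndim != 3:
        raise InvalidParameterError("vesselness_3d needs a 3D HessianField")
    lam1 = field.eigenvalues[..., 0]
    lam2 = field.eigenvalues[..., 1]
    lam3 = field.eigenvalues[..., 2]
    ra = anisotropy_ratio_3d(lam2, lam3)
    rb = blobness_ratio_3d(lam1, lam2, lam3)
    v = ((1.0 - np.exp(-(ra**2) / (2.0 * params.alpha**2)))
         * np.exp(-(rb**2) / (2.0 * params.beta**2))
         * _structureness_term(field, params))
    return np.where((lam2 > 0) | (lam3 > 0), 0.0, v)


def multiscale_enhance(image: np.ndarray, params: VesselnessParams | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Maximum vesselness over all scales plus the argmax scale map."""
    params = params or VesselnessParams()
    image = np.asarray(image, dtype=float)
    vessel_fn = vesselness_2d if image.ndim == 2 else vesselness_3d
    best = np.full(image.shape, -1.0)
    scale_map = np.zeros(image.shape)
    for s in params.scales:
        field = gaussian_hessian(image, s)
        v = vessel_fn(field, params)
        take = v > best
        best = np.where(take, v, best)
        scale_map = np.where(take, s, scale_map)
    return best, scale_map
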