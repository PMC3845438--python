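"""Synthetic tubular phantoms with known ground truth.

All generators are pure functions of their parameters and the random seed.
Tubes have a Gaussian cross-section (peak = background + contrast, width
parameter = radius) so that closed-form Hessian eigenvalues exist at the
centerline; the binary ground-truth mask is the set of pixels within
``radius`` of the centerline, computed before noise is added.

Gray convention: background level 60, 8-bit clipping to [0, 255].
Coordinates are 0-based, row-major.  In-plane angles are measured in
degrees from the +x (column) axis toward the +y (row) axis, folded to
[0°, 180°).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError

BACKGROUND_GRAY = 60.0


@dataclass
class CenterlineBranch:
    """One ordered run of centerline points with a parent link."""

    id: int
    parent: int | None
    points: np.ndarray  # (n, ndim) float, (row, col[, slice]) order

    def to_json(self) -> dict:
        return {
            "id": self.id,
            "parent": self.parent,
            "points": np.asarray(self.points).tolist(),
        }


@dataclass
class Phantom:
    """A synthetic gray image/volume plus its ground truth."""

    image: np.ndarray  # float32, values in [0, 255]
    mask: np.ndarray  # bool, pre-noise ground truth
    centerline: list[CenterlineBranch] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def ndim(self) -> int:
        return self.image.ndim


def _unit(angle_deg: float) -> np.ndarray:
    """Unit direction (dx, dy) for an in-plane angle in degrees."""
    t = np.deg2rad(angle_deg)
    return np.array([np.cos(t), np.sin(t)])


def _segment_distance(shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray):
    """Per-pixel Euclidean distance to the segment p0->p1 (points are (x, y))."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    px = cols - p0[0]
    py = rows - p0[1]
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0.0:
        return np.hypot(px, py)
    t = np.clip((px * d[0] + py * d[1]) / seg_len2, 0.0, 1.0)
    return np.hypot(px - t * d[0], py - t * d[1])


def _segment_points(p0: np.ndarray, p1: np.ndarray, shape) -> np.ndarray:
    """Unit-spaced (row, col) centerline samples along a segment, inside the image."""
    length = float(np.hypot(*(p1 - p0)))
    n = max(int(np.ceil(length)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    xy = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    pts = np.stack([xy[:, 1], xy[:, 0]], axis=1)  # (row, col)
    keep = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] <= shape[0] - 1)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] <= shape[1] - 1)
    )
    return pts[keep]


def _finalize(profile_sq: np.ndarray, mask: np.ndarray, radius: float,
              contrast: float, noise_sd: float, seed: int,
              centerline: list[CenterlineBranch], meta: dict) -> Phantom:
    """profile_sq holds the squared distance to the nearest centerline."""
    image = BACKGROUND_GRAY + contrast * np.exp(-profile_sq / (2.0 * radius**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 255.0).astype(np.float32)
    return Phantom(image=image, mask=mask, centerline=centerline, meta=meta)


def _check_tube_params(radius: float, contrast: float) -> None:
    if radius <= 0:
        raise InvalidParameterError(f"radius must be positive, got {radius}")
    if contrast <= 0:
        raise InvalidParameterError(f"contrast must be positive, got {contrast}")


def make_tube_2d(size: int, angle_deg: float, radius: float, contrast: float,
                 noise_sd: float = 0.0, seed: int = 0) -> Phantom:
    """A straight bright bar through the image center at ``angle_deg``.

    ``angle_deg`` = 0 gives a horizontal bar; 90 gives its transpose.
    """
    _check_tube_params(radius, contrast)
    if not (0 <= angle_deg < 180):
        raise InvalidParameterError("angle_deg must lie in [0, 180)")
    if size < 4 * radius:
        raise InvalidParameterError("image too small to contain the tube")
    c0 = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    x = cols - c0
    y = rows - c0
    t = np.deg2rad(angle_deg)
    # distance to the infinite line through center with direction (cos t, sin t)
    dist = np.abs(x * np.sin(t) - y * np.cos(t))
    mask = dist <= radius
    d = _unit(angle_deg) * size  # long enough to cross the image
    center = np.array([c0, c0])
    pts = _segment_points(center - d, center + d, (size, size))
    centerline = [CenterlineBranch(0, None, pts)]
    meta = {
        "kind": "tube2d", "size": size, "angle_deg": float(angle_deg),
        "radius": float(radius), "contrast": float(contrast),
        "noise_sd": float(noise_sd), "seed": int(seed),
        "background": BACKGROUND_GRAY,
    }
    return _finalize(dist**2, mask, radius, contrast, noise_sd, seed,
                     centerline, meta)


def _multi_segment_phantom(size: int, segments: list[tuple[np.ndarray, np.ndarray]],
                           parents: Sequence[int | None], radii: Sequence[float],
                           contrast: float, noise_sd: float, seed: int,
                           meta: dict) -> Phantom:
    shape = (size, size)
    # squared distance normalized per-segment radius: take the max Gaussian
    best = np.full(shape, np.inf)
    mask = np.zeros(shape, dtype=bool)
    centerline = []
    for i, ((p0, p1), parent, r) in enumerate(zip(segments, parents, radii)):
        dist = _segment_distance(shape, p0, p1)
        mask |= dist <= r
        # scale distances so one shared radius term can be used in _finalize
        best = np.minimum(best, (dist / r) ** 2)
        centerline.append(CenterlineBranch(i, parent, _segment_points(p0, p1, shape)))
    return _finalize(best, mask, 1.0, contrast, noise_sd, seed, centerline, meta)


def make_branch_2d(size: int, trunk_angle: float, branch_angle: float,
                   radius: float, contrast: float, noise_sd: float = 0.0,
                   seed: int = 0) -> Phantom:
    """A Y-shaped structure: a trunk splitting into two children.

    Children leave the bifurcation (image center) at ``trunk_angle`` ±
    ``branch_angle``.
    """
    _check_tube_params(radius, contrast)
    if branch_angle == 0:
        raise InvalidParameterError("branch_angle must be non-zero")
    c0 = (size - 1) / 2.0
    center = np.array([c0, c0])
    arm = 0.38 * size
    trunk_start = center - _unit(trunk_angle) * arm
    child_a = center + _unit(trunk_angle + branch_angle) * arm
    child_b = center + _unit(trunk_angle - branch_angle) * arm
    for p in (trunk_start, child_a, child_b):
        if not (0 <= p[0] <= size - 1 and 0 <= p[1] <= size - 1):
            raise InvalidParameterError("branch geometry exits the image")
    segments = [(trunk_start, center), (center, child_a), (center, child_b)]
    meta = {
        "kind": "branch2d", "size": size, "trunk_angle": float(trunk_angle),
        "branch_angle": float(branch_angle), "radius": float(radius),
        "contrast": float(contrast), "noise_sd": float(noise_sd),
        "seed": int(seed), "background": BACKGROUND_GRAY,
    }
    return _multi_segment_phantom(size, segments, [None, 0, 0],
                                  [radius] * 3, contrast, noise_sd, seed, meta)


def make_tree_2d(size: int, depth: int, radius_root: float, contrast: float,
                 noise_sd: float = 0.0, seed: int = 0,
                 spread_deg: float = 28.0) -> Phantom:
    """A recursive binary tree rooted at the bottom center, growing upward.

    Child radius is max(1, parent radius - 1); child length shrinks by 0.72
    per level.  Geometry is deterministic; ``seed`` only drives the noise.
    """
    _check_tube_params(radius_root, contrast)
    if depth < 1:
        raise InvalidParameterError("depth must be >= 1")
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    parents: list[int | None] = []
    radii: list[float] = []

    root_start = np.array([(size - 1) / 2.0, size * 0.92])
    root_len = size * 0.30

    def add(p0, angle, length, radius, parent, level):
        p1 = p0 + _unit(angle) * length
        if not (0 <= p1[0] <= size - 1 and 0 <= p1[1] <= size - 1):
            raise InvalidParameterError("tree depth degenerates outside the image")
        if length < 2 * radius:
            raise InvalidParameterError("tree depth degenerates segment length")
        idx = len(segments)
        segments.append((p0, p1))
        parents.append(parent)
        radii.append(radius)
        if level + 1 < depth:
            child_r = max(1.0, radius - 1.0)
            for sgn in (+1, -1):
                add(p1, angle + sgn * spread_deg, length * 0.72, child_r,
                    idx, level + 1)

    # angle 270° points toward decreasing row (upward)
    add(root_start, 270.0, root_len, radius_root, None, 0)
    meta = {
        "kind": "tree2d", "size": size, "depth": int(depth),
        "radius_root": float(radius_root), "contrast": float(contrast),
        "noise_sd": float(noise_sd), "seed": int(seed),
        "spread_deg": float(spread_deg), "background": BACKGROUND_GRAY,
    }
    return _multi_segment_phantom(size, segments, parents, radii, contrast,
                                  noise_sd, seed, meta)


def make_blob_sheet_tube_3d(size: int, kind: str, scale: float,
                            contrast: float, seed: int = 0) -> Phantom:
    """Centered 3D Gaussian blob, sheet (one thin axis), or tube (two thin axes).

    The tube runs along the last (x) axis; the sheet is thin along the first
    (z) axis.  Used to probe eigenvalue-ratio discrimination.
    """
    if kind not in ("blob", "sheet", "tube"):
        raise InvalidParameterError(f"kind must be blob|sheet|tube, got {kind!r}")
    if scale < 1:
        raise InvalidParameterError("scale must be >= 1")
    if contrast <= 0:
        raise InvalidParameterError("contrast must be positive")
    c0 = (size - 1) / 2.0
    z, y, x = np.mgrid[0:size, 0:size, 0:size].astype(float) - c0
    if kind == "blob":
        q = z**2 + y**2 + x**2
    elif kind == "sheet":
        q = z**2
    else:  # tube along x
        q = z**2 + y**2
    mask = q <= scale**2
    centerline = []
    if kind == "tube":
        pts = np.stack([np.full(size, c0), np.full(size, c0),
                        np.arange(size, dtype=float)], axis=1)
        centerline = [CenterlineBranch(0, None, pts)]
    meta = {"kind": kind, "size": size, "scale": float(scale),
            "contrast": float(contrast), "seed": int(seed),
            "background": BACKGROUND_GRAY}
    return _finalize(q, mask, scale, contrast, 0.0, seed, centerline, meta)


def save_phantom(phantom: Phantom, prefix: str) -> list[str]:
    """Write the image (PNG for 2D, NIfTI for 3D) plus a JSON sidecar."""
    paths = []
    if phantom.ndim == 2:
        import imageio.v3 as iio

        img_path = f"{prefix}.png"
        iio.imwrite(img_path, np.round(phantom.image).astype(np.uint8))
        mask_path = f"{prefix}_mask.png"
        iio.imwrite(mask_path, (phantom.mask.astype(np.uint8) * 255))
    else:
        import nibabel as nib

        img_path = f"{prefix}.nii"
        nib.save(nib.Nifti1Image(phantom.image.astype(np.float32), np.eye(4)),
                 img_path)
        mask_path = f"{prefix}_mask.nii"
        nib.save(nib.Nifti1Image(phantom.mask.astype(np.uint8), np.eye(4)),
                 mask_path)
    sidecar = f"{prefix}.json"
    with open(sidecar, "w") as fh:
        json.dump({"meta": phantom.meta,
                   "centerline": [b.to_json() for b in phantom.centerline]},
                  fh, indent=2)
    paths.extend([img_path, mask_path, sidecar])
    return paths
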