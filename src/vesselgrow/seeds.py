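"""Automatic seed selection inside detected vessels.

A cross-section is sampled perpendicular to the detected feature direction
through an anchor of high vesselness, matched-filtered with a zero-mean
Gaussian template, and the filtered maximum (away from edge pixels) becomes
the region-growing seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import InvalidParameterError, NoVesselError, SeedNotFoundError
from .spectrum import VesselDetection

__all__ = [
    "SeedCandidate",
    "CrossSection",
    "sobel_edges",
    "cross_section",
    "matched_filter",
    "select_seed",
    "select_seeds",
]


@dataclass
class SeedCandidate:
    """A selected seed point and the evidence behind it."""

    coords: tuple[int, ...]  # 0-based (row, col)
    roi_id: int
    direction: np.ndarray  # feature direction used, (x, y) unit vector
    profile: np.ndarray
    filtered: np.ndarray
    edge_distance: float

    def to_json(self) -> dict:
        return {
            "x": int(self.coords[1]),
            "y": int(self.coords[0]),
            "roi_id": int(self.roi_id),
            "direction": [float(v) for v in self.direction],
            "edge_distance": float(self.edge_distance),
        }


class CrossSection(NamedTuple):
    profile: np.ndarray
    coords: np.ndarray  # (n, 2) float (row, col) sample positions
    truncated: bool


def sobel_edges(image: np.ndarray, edge_threshold: float | None = None
                ) -> np.ndarray:
    """Binary edge map from the 3x3 Sobel gradient magnitude.

    With ``edge_threshold=None`` the threshold is chosen by Otsu's method on
    the magnitude image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidParameterError("sobel_edges expects a 2D image")
    gy = ndimage.sobel(image, axis=0, mode="reflect")
    gx = ndimage.sobel(image, axis=1, mode="reflect")
    mag = np.hypot(gx, gy)
    if edge_threshold is None:
        if np.allclose(mag, mag.flat[0]):
            return np.zeros(image.shape, dtype=bool)
        edge_threshold = threshold_otsu(mag)
    return mag > edge_threshold


def cross_section(image: np.ndarray, anchor: tuple[float, float],
                  direction: np.ndarray, half_length: int) -> CrossSection:
    """Bilinear gray samples along the line perpendicular to ``direction``.

    ``direction`` is the (x, y) feature direction of the structure; samples
    are taken at unit spacing, 2*half_length + 1 in total, centered on the
    anchor.  If the segment exits the image the profile is truncated and the
    flag set.
    """
    direction = np.asarray(direction, dtype=float)
    nrm = np.hypot(*direction)
    if nrm == 0:
        raise InvalidParameterError("direction must be non-zero")
    dx, dy = direction / nrm
    px, py = -dy, dx  # perpendicular
    t = np.arange(-half_length, half_length + 1, dtype=float)
    rows = anchor[0] + t * py
    cols = anchor[1] + t * px
    inside = ((rows >= 0) & (rows <= image.shape[0] - 1)
              & (cols >= 0) & (cols <= image.shape[1] - 1))
    truncated = not bool(inside.all())
    rows, cols = rows[inside], cols[inside]
    profile = ndimage.map_coordinates(np.asarray(image, dtype=float),
                                      np.stack([rows, cols]), order=1,
                                      mode="nearest")
    return CrossSection(profile=profile,
                        coords=np.stack([rows, cols], axis=1),
                        truncated=truncated)


def matched_filter(profile: np.ndarray, kernel_sigma: float) -> np.ndarray:
    """1D correlation with a zero-mean Gaussian template (reflect padding)."""
    profile = np.asarray(profile, dtype=float)
    half = max(1, int(np.ceil(3 * kernel_sigma)))
    if profile.size < 2 * half + 1:
        raise InvalidParameterError("profile shorter than the kernel support")
    x = np.arange(-half, half + 1, dtype=float)
    template = np.exp(-(x**2) / (2.0 * kernel_sigma**2))
    template -= template.mean()
    padded = np.pad(profile, half, mode="reflect")
    return np.correlate(padded, template, mode="valid")


def select_seed(image: np.ndarray, roi: tuple[slice, slice],
                detection: VesselDetection,
                edges: np.ndarray | None = None,
                vesselness: np.ndarray | None = None,
                kernel_sigma: float = 2.0,
                half_length: int | None = None,
                roi_id: int = 0) -> SeedCandidate:
    """Pick the seed on the matched-filtered cross-section maximum.

    The anchor is the highest-vesselness pixel inside the ROI (highest gray
    value when no vesselness map is supplied); the cut runs perpendicular to
    the detected feature direction.  Candidates landing on Sobel edge pixels
    are rejected and the next-best filtered maximum is tried.
    """
    if not detection.detected or detection.primary_direction is None:
        raise NoVesselError("no vessel detected in the ROI")
    image = np.asarray(image, dtype=float)
    if edges is None:
        edges = sobel_edges(image)
    score = image if vesselness is None else np.asarray(vesselness, dtype=float)
    sub = score[roi]
    flat = int(np.argmax(sub))
    local = np.unravel_index(flat, sub.shape)
    anchor = (roi[0].start + local[0], roi[1].start + local[1])
    if half_length is None:
        half_length = max(4, min(sub.shape) // 2 - 1)
    section = cross_section(image, anchor, detection.primary_direction,
                            half_length)
    filtered = matched_filter(section.profile, kernel_sigma)
    edge_dist_map = ndimage.distance_transform_edt(~edges)
    r0, r1 = roi[0].start, roi[0].stop
    c0, c1 = roi[1].start, roi[1].stop
    for idx in np.argsort(filtered, kind="stable")[::-1]:
        r, c = section.coords[idx]
        pr, pc = int(round(r)), int(round(c))
        if not (r0 < pr < r1 - 1 and c0 < pc < c1 - 1):
            continue  # seed must lie strictly inside the ROI
        if edges[pr, pc]:
            continue
        return SeedCandidate(coords=(pr, pc), roi_id=roi_id,
                             direction=np.asarray(detection.primary_direction),
                             profile=section.profile, filtered=filtered,
                             edge_distance=float(edge_dist_map[pr, pc]))
    raise SeedNotFoundError("all cross-section maxima fall on edge pixels")


def select_seeds(image: np.ndarray, roi: tuple[slice, slice],
                 detection: VesselDetection,
                 edges: np.ndarray | None = None,
                 vesselness: np.ndarray | None = None,
                 kernel_sigma: float = 2.0,
                 half_length: int | None = None,
                 roi_id: int = 0) -> list[SeedCandidate]:
    """One seed per detected feature direction (primary + sub-primary)."""
    if not detection.detected:
        raise NoVesselError("no vessel detected in the ROI")
    directions = [detection.primary_direction] + [
        vec for _, vec in detection.secondary_directions
    ]
    out = []
    for vec in directions:
        sub = VesselDetection(detected=True, primary_direction=vec,
                              peak_theta=detection.peak_theta)
        try:
            out.append(select_seed(image, roi, sub, edges=edges,
                                   vesselness=vesselness,
                                   kernel_sigma=kernel_sigma,
                                   half_length=half_length, roi_id=roi_id))
        except SeedNotFoundError:
            continue
    if not out:
        raise SeedNotFoundError("no seed found for any direction")
    return out
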