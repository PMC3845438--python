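"""Branch-based region growing with dynamic per-branch thresholds.

Growth proceeds in integer cycles from a seed.  Each cycle expands the
current front by a neighborhood shell (optionally of step 2), accepts the
candidates passing the branch's gray test, and partitions the accepted
pixels into connected components.  When more than one component appears,
one branch continues and the rest are deferred on a LIFO stack until the
active branch stops; deferred fronts resume as child branches with their
own statistics.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, InvalidSeedError

__all__ = [
    "GrowthParams",
    "BranchRecord",
    "VesselSegmentation",
    "grow",
    "detect_branches",
    "accept_pixel",
    "branch_reference_gray",
    "estimate_thickness",
    "branch_count_experiment",
]


@dataclass
class GrowthParams:
    """Knobs of the branch-based growth.

    ``neighborhood`` is 4/8 in 2D or 6/26 in 3D; ``step`` expands the
    candidate shell to Chebyshev (8/26) or Manhattan (4/6) radius ``step``.
    ``c_min``/``c_max`` default to the 5th/99th gray percentile inside a
    dilated neighborhood of the seed.  ``k`` couples the branch reference
    gray to its thickness; with k = 0 all branches share c_min.
    """

    neighborhood: int = 8
    step: int = 2
    h: float = 2.0
    c_min: float | None = None
    c_max: float | None = None
    k: float = 0.0
    d_c: float = 10.0
    max_cycles: int | None = None  # default: image diagonal in pixels
    window: int = 200  # running-statistics window per branch
    eq10_continuous: bool = False  # thick-branch reference uses c_min
    # spread used in the acceptance test:
    #   "noise"    - robust image-noise estimate (default; avoids the runaway
    #                feedback a running std exhibits on smooth-profile vessels)
    #   "running"  - running std of the branch window
    #   "constant" - fixed value given by sigma_constant
    sigma_mode: str = "noise"
    sigma_constant: float | None = None

    def __post_init__(self):
        if self.neighborhood not in (4, 8, 6, 26):
            raise InvalidParameterError("neighborhood must be one of 4, 8, 6, 26")
        if self.step not in (1, 2):
            raise InvalidParameterError("step must be 1 or 2")
        if self.sigma_mode not in ("noise", "running", "constant"):
            raise InvalidParameterError("sigma_mode must be noise|running|constant")
        if self.sigma_mode == "constant" and self.sigma_constant is None:
            raise InvalidParameterError("sigma_mode=constant needs sigma_constant")
        if self.h < 0 or self.k < 0 or self.d_c <= 0:
            raise InvalidParameterError("h, k must be >= 0 and d_c > 0")
        if (self.c_min is not None and self.c_max is not None
                and self.c_min > self.c_max):
            raise InvalidParameterError("c_min must not exceed c_max")


@dataclass
class BranchRecord:
    """Bookkeeping for one grown branch."""

    id: int
    parent: int | None
    founding_cycle: int
    pixels: list = field(default_factory=list)  # flat indices
    grays: deque = field(default_factory=deque)  # acceptance-window grays
    n_cycles: int = 0
    thickness: float = 0.0

    @property
    def mean(self) -> float:
        return float(np.mean(self.grays)) if self.grays else 0.0

    @property
    def spread(self) -> float:
        return float(np.std(self.grays)) if len(self.grays) > 1 else 0.0

    def to_json(self) -> dict:
        return {
            "id": self.id,
            "parent": self.parent,
            "founding_cycle": self.founding_cycle,
            "n_pixels": len(self.pixels),
            "mean_gray": self.mean,
            "thickness": self.thickness,
        }


@dataclass
class VesselSegmentation:
    """Final mask, per-pixel growth-cycle map, and branch tree."""

    mask: np.ndarray  # bool
    cycle_map: np.ndarray  # int32, 0 = unvisited, 1 = seed
    branches: list[BranchRecord]
    truncated: bool = False

    def branch_tree_json(self) -> list[dict]:
        return [b.to_json() for b in self.branches]


def accept_pixel(g: float, mu: float, sigma: float, h: float) -> bool:
    """Gray acceptance test: g >= mu - h*sigma."""
    return bool(g >= mu - h * sigma)


def branch_reference_gray(d_i: float, params: GrowthParams) -> float:
    """Thickness-dependent reference gray for a branch.

    Thin branches (d_i < d_c) use c_min + k*d_i; thick ones use the printed
    c_max + k*d_c, or c_min + k*d_c with ``eq10_continuous``.
    """
    if d_i < 0:
        raise InvalidParameterError("thickness must be non-negative")
    c_min = params.c_min if params.c_min is not None else 0.0
    c_max = params.c_max if params.c_max is not None else 255.0
    if d_i < params.d_c:
        return c_min + params.k * d_i
    base = c_min if params.eq10_continuous else c_max
    return base + params.k * params.d_c


def estimate_thickness(branch_pixels: np.ndarray, mask: np.ndarray) -> float:
    """Average thickness of a branch from the mask's distance transform.

    Calibrated so a 1-pixel-wide line reports ~1 and a tube of width w
    reports ~w: d_i = 4 * mean(EDT over the branch pixels) - 3.
    """
    if len(branch_pixels) == 0:
        raise InvalidParameterError("branch has no pixels")
    edt = ndimage.distance_transform_edt(mask)
    flat = np.asarray(branch_pixels)
    vals = edt.reshape(-1)[flat]
    return max(float(4.0 * vals.mean() - 3.0), 0.0)


def _offsets(ndim: int, neighborhood: int, step: int) -> np.ndarray:
    full = neighborhood in (8, 26)
    offs = []
    for o in itertools.product(range(-step, step + 1), repeat=ndim):
        if all(v == 0 for v in o):
            continue
        dist = max(abs(v) for v in o) if full else sum(abs(v) for v in o)
        if dist <= step:
            offs.append(o)
    return np.array(offs, dtype=np.int64)


def _label_structure(ndim: int, neighborhood: int) -> np.ndarray:
    order = ndim if neighborhood in (8, 26) else 1
    return ndimage.generate_binary_structure(ndim, order)


def detect_branches(new_pixels: np.ndarray, neighborhood: int,
                    shape: tuple[int, ...] | None = None) -> list[np.ndarray]:
    """Partition same-cycle pixels into connected components.

    ``new_pixels`` is an (n, ndim) integer coordinate array; more than one
    returned component signals a bifurcation.
    """
    pts = np.asarray(new_pixels, dtype=np.int64)
    if pts.size == 0:
        return []
    ndim = pts.shape[1]
    lo = pts.min(axis=0)
    local = pts - lo
    box = np.zeros(local.max(axis=0) + 1, dtype=bool)
    box[tuple(local.T)] = True
    labels, n = ndimage.label(box, structure=_label_structure(ndim, neighborhood))
    lab = labels[tuple(local.T)]
    return [pts[lab == i] for i in range(1, n + 1)]


def _component_sort_key(comp: np.ndarray, shape) -> tuple:
    flat = np.ravel_multi_index(tuple(comp.T), shape)
    return (-len(comp), int(flat.min()))


def _seed_bounds(image: np.ndarray, seed: tuple[int, ...], radius: int = 8
                 ) -> tuple[float, float]:
    """Gray bounds of the region of interest from the seed's neighborhood.

    c_min separates vessel from background by Otsu's threshold on a dilated
    seed patch (falls back to the 5th percentile when the patch is
    single-class); c_max is the patch maximum.
    """
    sl = tuple(slice(max(0, s - radius), min(n, s + radius + 1))
               for s, n in zip(seed, image.shape))
    patch = image[sl]
    # background from the global median (vessels are sparse), local peak
    # from the seed patch; the boundary of a Gaussian-profile tube sits at
    # the 1-sigma gray level above background
    bg = float(np.median(image))
    peak = float(patch.max())
    lo = bg + np.exp(-0.5) * max(peak - bg, 0.0)
    return lo, peak


def estimate_noise_sd(image: np.ndarray) -> float:
    """Robust additive-noise estimate from the median absolute Laplacian.

    Smooth structure contributes little to the Laplacian away from edges, so
    the MAD of the discrete Laplacian, scaled for the kernel's noise gain and
    to the Gaussian sigma, tracks the i.i.d. noise level.
    """
    image = np.asarray(image, dtype=float)
    lap = ndimage.laplace(image, mode="reflect")
    mad = float(np.median(np.abs(lap - np.median(lap))))
    # Var(laplacian of iid noise) = (4d^2 + 2d) sigma^2; MAD factor 1.4826
    gain = 4.0 * image.ndim**2 + 2.0 * image.ndim
    return mad * 1.4826 / np.sqrt(gain)


def grow(image: np.ndarray, seed: tuple[int, ...],
         params: GrowthParams | None = None) -> VesselSegmentation:
    """Branch-based region growing from a single seed."""
    params = params or GrowthParams()
    image = np.asarray(image, dtype=float)
    ndim = image.ndim
    if ndim == 2 and params.neighborhood in (6, 26):
        raise InvalidParameterError("2D growth needs neighborhood 4 or 8")
    if ndim == 3 and params.neighborhood in (4, 8):
        raise InvalidParameterError("3D growth needs neighborhood 6 or 26")
    seed = tuple(int(s) for s in seed)
    if len(seed) != ndim or not all(0 <= s < n for s, n in zip(seed, image.shape)):
        raise InvalidParameterError("seed outside the image")

    c_min, c_max = params.c_min, params.c_max
    if c_min is None or c_max is None:
        lo, hi = _seed_bounds(image, seed)
        c_min = lo if c_min is None else c_min
        c_max = hi if c_max is None else c_max
    eff = GrowthParams(neighborhood=params.neighborhood, step=params.step,
                       h=params.h, c_min=c_min, c_max=c_max, k=params.k,
                       d_c=params.d_c, max_cycles=params.max_cycles,
                       window=params.window,
                       eq10_continuous=params.eq10_continuous,
                       sigma_mode=params.sigma_mode,
                       sigma_constant=params.sigma_constant)
    if eff.sigma_mode == "noise":
        noise_sigma = estimate_noise_sd(image)
    elif eff.sigma_mode == "constant":
        noise_sigma = float(eff.sigma_constant)
    else:
        noise_sigma = None  # running std per branch

    g_seed = image[seed]
    if not (c_min <= g_seed <= c_max):
        raise InvalidSeedError(
            f"seed gray {g_seed} outside the region of interest "
            f"[{c_min}, {c_max}]")

    max_cycles = params.max_cycles
    if max_cycles is None:
        max_cycles = int(np.ceil(np.sqrt(sum(n**2 for n in image.shape)))) * 4

    shape = image.shape
    flat_img = image.reshape(-1)
    cycle_map = np.zeros(shape, dtype=np.int32)
    cycle_map[seed] = 1
    visited = np.zeros(flat_img.shape, dtype=bool)
    seed_flat = int(np.ravel_multi_index(seed, shape))
    visited[seed_flat] = True

    offsets = _offsets(ndim, eff.neighborhood, eff.step)

    # warm-up statistics start from the seed's immediate neighborhood so a
    # noisy seed outlier cannot stall the first cycle
    patch_sl = tuple(slice(max(0, s - 1), min(n, s + 2))
                     for s, n in zip(seed, shape))
    root = BranchRecord(id=0, parent=None, founding_cycle=1,
                        pixels=[seed_flat],
                        grays=deque(image[patch_sl].ravel(), maxlen=eff.window))
    branches = [root]
    stack: list[tuple[int, np.ndarray]] = []  # (branch id, front coords)
    active_id = 0
    front = np.array([seed], dtype=np.int64)
    cycle = 1
    truncated = False

    while True:
        if cycle >= max_cycles:
            truncated = True
            break
        branch = branches[active_id]
        # candidate shell around the front
        cand = (front[:, None, :] + offsets[None, :, :]).reshape(-1, ndim)
        ok = np.all((cand >= 0) & (cand < np.array(shape)), axis=1)
        cand = cand[ok]
        if cand.size:
            flat = np.ravel_multi_index(tuple(cand.T), shape)
            flat = np.unique(flat)
            flat = flat[~visited[flat]]
        else:
            flat = np.empty(0, dtype=np.int64)

        accepted = np.empty(0, dtype=np.int64)
        if flat.size:
            # warm-up cycles track the running branch mean; once the branch
            # is established its reference gray switches to the
            # thickness-dependent piecewise form
            # branch reference gray via the thickness-dependent piecewise
            # form (thickness re-estimated once the branch is established)
            if eff.k > 0 and branch.n_cycles >= 3:
                branch.thickness = estimate_thickness(
                    np.array(branch.pixels), cycle_map.astype(bool))
            mu = branch_reference_gray(branch.thickness, eff)
            sigma = branch.spread if noise_sigma is None else noise_sigma
            accepted = flat[flat_img[flat] >= mu - eff.h * sigma]

        if accepted.size == 0:
            if not stack:
                break
            active_id, front = stack.pop()
            cycle += 1
            continue

        cycle += 1
        visited[accepted] = True
        coords = np.stack(np.unravel_index(accepted, shape), axis=1)
        cycle_map.reshape(-1)[accepted] = cycle
        if eff.step == 2:
            # step-2 joint-edge rule: connectivity is judged on the last two
            # growth cycles together, which merges ragged same-cycle
            # fragments that are bridged by the previous front
            joint = np.vstack([coords, front])
            joint_comps = detect_branches(joint, eff.neighborhood)
            accepted_set = set(accepted.tolist())
            comps = []
            for comp in joint_comps:
                comp_flat = np.ravel_multi_index(tuple(comp.T), shape)
                keep = np.fromiter((f in accepted_set for f in comp_flat),
                                   dtype=bool, count=len(comp_flat))
                if keep.any():
                    comps.append(comp[keep])
        else:
            comps = detect_branches(coords, eff.neighborhood)
        comps.sort(key=lambda c: _component_sort_key(c, shape))
        if len(comps) == 1:
            cont = comps[0]
            cont_flat = np.ravel_multi_index(tuple(cont.T), shape)
            branch.pixels.extend(cont_flat)
            branch.grays.extend(flat_img[cont_flat])
            branch.n_cycles += 1
            front = cont
        else:
            # bifurcation: the parent stops; every component becomes a child
            # branch, the largest continues and the rest are deferred LIFO
            children = []
            for comp in comps:
                comp_flat = np.ravel_multi_index(tuple(comp.T), shape)
                child = BranchRecord(
                    id=len(branches), parent=active_id, founding_cycle=cycle,
                    pixels=list(comp_flat),
                    grays=deque(flat_img[comp_flat], maxlen=eff.window),
                    thickness=branch.thickness)
                branches.append(child)
                children.append((child, comp))
            for child, comp in children[1:]:
                stack.append((child.id, comp))
            active_id = children[0][0].id
            front = children[0][1]

    # final thickness estimates
    mask = cycle_map > 0
    for b in branches:
        if b.pixels:
            b.thickness = estimate_thickness(np.array(b.pixels), mask)

    return VesselSegmentation(mask=mask, cycle_map=cycle_map,
                              branches=branches, truncated=truncated)


def branch_count_experiment(image: np.ndarray, seed: tuple[int, ...],
                            configs: list[tuple[int, int]],
                            **grow_kwargs) -> list[dict]:
    """Run growth under several (step, neighborhood) configs; report counts."""
    out = []
    for step, neigh in configs:
        params = GrowthParams(neighborhood=neigh, step=step, **grow_kwargs)
        seg = grow(image, seed, params)
        out.append({"step": step, "neighborhood": neigh,
                    "n_branches": len(seg.branches)})
    return out
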