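"""Pipeline driver: configuration, image IO, stage orchestration, metrics.

The full run is enhance -> spectral detection on overlapping ROI tiles ->
seed selection -> branch-based growing, with every stage's parameters and
outputs recorded in a JSON run report for reproducibility.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import enhancement, growing, seeds, spectrum
from .errors import (InvalidParameterError, InvalidSeedError, NoVesselError,
                     SeedNotFoundError)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "evaluate",
    "load_image",
    "save_image",
    "tile_rois",
]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; serializable to YAML/JSON."""

    input_path: str = ""
    output_dir: str = "."
    mode: str = "2d"  # 2d | 3d-slicewise | 3d
    # enhancement
    scales: tuple[float, ...] = enhancement.DEFAULT_SCALES
    alpha: float = 0.5
    beta: float = 0.5
    c: float | None = None
    skip_enhancement: bool = False
    # spectrum
    dtheta: float = 1.0
    omega: float = 5.0
    detect_threshold: float = spectrum.DEFAULT_DETECT_THRESHOLD
    window: bool = True
    direction_formula: str = "literal"
    tile: int = 64
    tile_overlap: float = 0.5
    # seeds
    edge_threshold: float | None = None
    kernel_sigma: float | None = None  # None: argmax scale at anchor / 2
    # growing
    neighborhood: int = 8
    step: int = 2
    h: float = 2.0
    c_min: float | None = None
    c_max: float | None = None
    k: float = 0.0
    d_c: float = 10.0
    sigma_mode: str = "noise"
    sigma_constant: float | None = None
    max_cycles: int | None = None
    # misc
    rescale_gray: bool = True
    random_seed: int = 0
    verbosity: int = 0

    def validate(self) -> None:
        if self.mode not in ("2d", "3d-slicewise", "3d"):
            raise InvalidParameterError("mode must be 2d|3d-slicewise|3d")
        if not (0 <= self.tile_overlap < 1):
            raise InvalidParameterError("tile_overlap must be in [0, 1)")
        if self.tile < 8:
            raise InvalidParameterError("tile must be >= 8")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["scales"] = list(self.scales)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "scales" in data:
            data["scales"] = tuple(float(s) for s in data["scales"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def as_dict(self) -> dict:
        d = asdict(self)
        d["scales"] = list(self.scales)
        return d


def load_image(path: str | Path, rescale: bool = True) -> np.ndarray:
    """Read a 2D image (PNG/TIFF) or 3D volume (NIfTI/TIFF stack).

    Inputs deeper than 8 bits are min-max rescaled to [0, 255] (disable with
    ``rescale=False``); 8-bit inputs are passed through unchanged.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    elif suffixes.endswith((".tif", ".tiff")):
        import tifffile

        data = tifffile.imread(str(path)).astype(float)
    else:
        import imageio.v3 as iio

        data = iio.imread(str(path)).astype(float)
        if data.ndim == 3 and data.shape[-1] in (3, 4):  # RGB(A) -> gray
            data = data[..., :3].mean(axis=-1)
    if rescale and data.max() > 255:
        lo, hi = float(data.min()), float(data.max())
        data = (data - lo) / (hi - lo) * 255.0 if hi > lo else data * 0.0
    return data


def save_image(array: np.ndarray, path: str | Path) -> None:
    """Write PNG/TIFF for 2D, NIfTI for 3D; dtype chosen from the suffix use."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(array), np.eye(4)), str(path))
    elif suffixes.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), np.asarray(array))
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), np.asarray(array))


def tile_rois(shape: tuple[int, int], tile: int = 64, overlap: float = 0.5
              ) -> list[tuple[slice, slice]]:
    """Overlapping square ROI tiling covering the whole 2D image."""
    stride = max(1, int(round(tile * (1.0 - overlap))))
    rois = []
    for r0 in _tile_starts(shape[0], tile, stride):
        for c0 in _tile_starts(shape[1], tile, stride):
            rois.append((slice(r0, min(r0 + tile, shape[0])),
                         slice(c0, min(c0 + tile, shape[1]))))
    return rois


def _tile_starts(n: int, tile: int, stride: int) -> list[int]:
    if n <= tile:
        return [0]
    starts = list(range(0, n - tile + 1, stride))
    if starts[-1] != n - tile:
        starts.append(n - tile)
    return starts


def evaluate(mask: np.ndarray, reference: np.ndarray) -> dict:
    """Pixel accuracy, Dice, sensitivity, and specificity vs a reference."""
    mask = np.asarray(mask, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if mask.shape != reference.shape:
        raise InvalidParameterError("mask and reference shapes differ")
    tp = float(np.count_nonzero(mask & reference))
    tn = float(np.count_nonzero(~mask & ~reference))
    fp = float(np.count_nonzero(mask & ~reference))
    fn = float(np.count_nonzero(~mask & reference))
    total = tp + tn + fp + fn
    return {
        "accuracy": (tp + tn) / total if total else 0.0,
        "dice": 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0,
        "sensitivity": tp / (tp + fn) if (tp + fn) else 1.0,
        "specificity": tn / (tn + fp) if (tn + fp) else 1.0,
    }


def _segment_2d(image: np.ndarray, config: PipelineConfig, report: dict):
    """Shared 2D stage chain: enhance, tile-detect, seed, grow."""
    t0 = time.perf_counter()
    if config.skip_enhancement:
        vmap, scale_map = None, None
    else:
        params = enhancement.VesselnessParams(alpha=config.alpha,
                                              beta=config.beta, c=config.c,
                                              scales=config.scales)
        vmap, scale_map = enhancement.multiscale_enhance(image, params)
    report["timings"]["enhance"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    edge_map = seeds.sobel_edges(image, config.edge_threshold)
    rois = tile_rois(image.shape, config.tile, config.tile_overlap)
    detections = []
    seed_list = []
    for roi_id, roi in enumerate(rois):
        spec = spectrum.dft2(image[roi], window=config.window)
        profile = spectrum.angular_energy_profile(spec, config.dtheta,
                                                  config.omega, power=2)
        det = spectrum.detect_vessel(profile, config.detect_threshold,
                                     config.direction_formula)
        detections.append((roi, det))
        if not det.detected:
            continue
        if config.kernel_sigma is None and scale_map is not None:
            sub = (vmap[roi], scale_map[roi])
            anchor = np.unravel_index(int(np.argmax(sub[0])), sub[0].shape)
            ksigma = max(0.5, float(sub[1][anchor]) / 2.0)
        else:
            ksigma = config.kernel_sigma or 2.0
        try:
            found = seeds.select_seeds(image, roi, det, edges=edge_map,
                                       vesselness=vmap, kernel_sigma=ksigma,
                                       roi_id=roi_id)
        except (SeedNotFoundError, NoVesselError):
            continue
        seed_list.extend(found)
    report["timings"]["detect_and_seed"] = time.perf_counter() - t0
    report["n_rois"] = len(rois)
    report["n_detected_rois"] = sum(1 for _, d in detections if d.detected)
    report["n_seeds"] = len(seed_list)

    if not seed_list:
        raise NoVesselError("no vessel detected in any ROI")

    t0 = time.perf_counter()
    gparams = growing.GrowthParams(
        neighborhood=config.neighborhood, step=config.step, h=config.h,
        c_min=config.c_min, c_max=config.c_max, k=config.k, d_c=config.d_c,
        max_cycles=config.max_cycles, sigma_mode=config.sigma_mode,
        sigma_constant=config.sigma_constant)
    mask = np.zeros(image.shape, dtype=bool)
    cycle_map = np.zeros(image.shape, dtype=np.int32)
    branch_tree: list[dict] = []
    used_seeds = []
    for cand in seed_list:
        if mask[cand.coords]:
            continue  # already reached by an earlier growth
        try:
            seg = growing.grow(image, cand.coords, gparams)
        except InvalidSeedError:
            continue
        new = seg.mask & ~mask
        if new.sum() == 0:
            continue
        offset = len(branch_tree)
        for b in seg.branches:
            rec = b.to_json()
            rec["id"] += offset
            if rec["parent"] is not None:
                rec["parent"] += offset
            rec["from_seed"] = list(cand.coords)
            branch_tree.append(rec)
        cycle_map = np.where(mask, cycle_map, seg.cycle_map)
        mask |= seg.mask
        used_seeds.append(cand)
    report["timings"]["grow"] = time.perf_counter() - t0
    report["n_branches"] = len(branch_tree)
    return mask, cycle_map, branch_tree, used_seeds, detections


def run_pipeline(config: PipelineConfig,
                 image: np.ndarray | None = None) -> dict:
    """Execute the full segmentation pipeline and write all outputs.

    Returns a result dict with the mask, cycle map, branch tree, seeds, and
    the run report.  ``image`` overrides ``config.input_path`` (useful for
    in-memory phantoms).
    """
    config.validate()
    if image is None:
        image = load_image(config.input_path, rescale=config.rescale_gray)
    image = np.asarray(image, dtype=float)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.as_dict(), "timings": {},
                    "image_shape": list(image.shape)}

    if config.mode == "2d":
        if image.ndim != 2:
            raise InvalidParameterError("mode 2d needs a 2D image")
        mask, cycle_map, tree, used_seeds, detections = _segment_2d(
            image, config, report)
    elif config.mode == "3d-slicewise":
        if image.ndim != 3:
            raise InvalidParameterError("mode 3d-slicewise needs a volume")
        mask = np.zeros(image.shape, dtype=bool)
        cycle_map = np.zeros(image.shape, dtype=np.int32)
        tree = []
        used_seeds = []
        detections = []
        for z in range(image.shape[0]):
            sub_report = {"timings": {}}
            try:
                m, c, t, s, d = _segment_2d(image[z], config, sub_report)
            except NoVesselError:
                continue
            mask[z] = m
            cycle_map[z] = c
            for rec in t:
                rec["slice"] = z
            tree.extend(t)
            used_seeds.extend(s)
            detections.extend(d)
        if not tree:
            raise NoVesselError("no vessel detected in any slice")
    else:  # full 3D: spectral detection is 2D-only, so seed via mid-slice
        if image.ndim != 3:
            raise InvalidParameterError("mode 3d needs a volume")
        mid = image.shape[0] // 2
        sub_report = {"timings": {}}
        _, _, _, used_seeds, detections = _segment_2d(image[mid], config,
                                                      sub_report)
        report["timings"].update(sub_report["timings"])
        gparams = growing.GrowthParams(
            neighborhood=26 if config.neighborhood == 8 else config.neighborhood,
            step=config.step, h=config.h, c_min=config.c_min,
            c_max=config.c_max, k=config.k, d_c=config.d_c,
            max_cycles=config.max_cycles, sigma_mode=config.sigma_mode,
            sigma_constant=config.sigma_constant)
        mask = np.zeros(image.shape, dtype=bool)
        cycle_map = np.zeros(image.shape, dtype=np.int32)
        tree = []
        for cand in used_seeds:
            seed3 = (mid,) + tuple(cand.coords)
            if mask[seed3]:
                continue
            try:
                seg = growing.grow(image, seed3, gparams)
            except InvalidSeedError:
                continue
            offset = len(tree)
            for b in seg.branches:
                rec = b.to_json()
                rec["id"] += offset
                if rec["parent"] is not None:
                    rec["parent"] += offset
                tree.append(rec)
            cycle_map = np.where(mask, cycle_map, seg.cycle_map)
            mask |= seg.mask

    # ---- outputs ----
    is3d = mask.ndim == 3
    ext = ".nii" if is3d else ".png"
    save_image((mask.astype(np.uint8) * 255), out / f"mask{ext}")
    save_image(cycle_map.astype(np.uint16), out / f"cycle_map{ext}")
    (out / "branch_tree.json").write_text(json.dumps(tree, indent=2))
    (out / "seeds.json").write_text(json.dumps(
        [s.to_json() for s in used_seeds], indent=2))
    det_json = [{"roi": [[sl.start, sl.stop] for sl in roi],
                 **det.to_json()} for roi, det in detections]
    (out / "detections.json").write_text(json.dumps(det_json, indent=2))
    report["n_mask_pixels"] = int(mask.sum())
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return {"mask": mask, "cycle_map": cycle_map, "branch_tree": tree,
            "seeds": used_seeds, "report": report}
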