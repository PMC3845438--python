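# vesselgrow

Spectrum-guided, branch-based region-growing vessel segmentation for 2D
grayscale images and 3D volumes.

The pipeline has four stages:

1. **Enhancement** (`vesselgrow.enhancement`) — multiscale Hessian vessel
   enhancement: eigenvalues of the Gaussian-smoothed Hessian, ordered by
   magnitude, feed geometric blobness/anisotropy ratios and a structureness
   term; responses over scales {1, 3, 5, 7} are fused by a pointwise
   maximum together with an argmax scale map.
2. **Spectral detection** (`vesselgrow.spectrum`) — a bright tube produces a
   bright line in the centered 2D DFT magnitude perpendicular to the tube.
   Summing spectral weight over angular wedges yields an angular energy
   profile; its peaks encode structure orientations and a trough-peak-trough
   slope test decides whether a tube is present.
3. **Seed selection** (`vesselgrow.seeds`) — Sobel edges, a cross-section cut
   perpendicular to the detected feature direction through a
   high-vesselness anchor, matched-filtered with a zero-mean Gaussian; the
   filtered maximum away from edge pixels becomes the seed.
4. **Branch-based growing** (`vesselgrow.growing`) — region growing in
   integer cycles with an 8/26-neighborhood and step-2 expansion. Accepted
   same-cycle pixels are partitioned into connected components; at a
   bifurcation one component continues and the rest are deferred on a LIFO
   stack until the active branch stops. Acceptance thresholds are dynamic
   per branch (`g >= mu_i - h*sigma` with a thickness-dependent reference
   gray `mu_i`).

Synthetic tubular phantoms with exact ground truth (`vesselgrow.phantoms`)
make every stage testable without external data: straight tubes, Y-branches,
recursive trees (2D) and blob/sheet/tube Gaussians (3D), all with Gaussian
cross-sections so closed-form Hessian oracles exist.

## CLI

```sh
# generate a phantom with ground truth + JSON sidecar
vesselgrow phantom --kind tree --size 128 --depth 3 --radius 3 \
    --noise-sd 5 -o /tmp/tree

# full pipeline: enhance -> detect -> seed -> grow
vesselgrow run /tmp/tree.png -o /tmp/out

# compare the produced mask with the ground truth
vesselgrow eval /tmp/out/mask.png /tmp/tree_mask.png
```

Individual stages are exposed as `vesselgrow enhance|detect|seed|grow`;
`vesselgrow run --config cfg.yaml` drives everything from a single YAML
file (see `vesselgrow.pipeline.PipelineConfig`). A run writes `mask.png`
(or `.nii`), `cycle_map`, `branch_tree.json`, `seeds.json`,
`detections.json`, and a `report.json` capturing the exact parameter set.
If no vessel is detected anywhere the CLI exits with status 3 and an empty
mask. Coordinates are 0-based row-major everywhere.

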