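# srusval

Super-resolution ultrasound (ULM) track mapping and quantitative comparison
against 3D micro-CT-like vascular volumes, exercised end to end on a
synthetic kidney vascular phantom that carries full ground truth.

The package covers five stages:

1. **`srusval.phantom`** — synthetic kidney-like vascular phantom: a branching
   arterial tree with paired (offset, wider) veins and parallel vasa-recta
   bundles; microbubble transport with pulsatile arterial flow; rendering of
   2D contrast frame stacks (Gaussian PSF + noise); smooth periodic tissue
   motion fields with matching speckle frames; rasterization of a
   contrast-cast CT-like volume. Every operation is a pure function of
   (inputs, seed).
2. **`srusval.ulm`** — the ULM processing chain: threshold + weighted-centroid
   bubble localization, block-matching speckle-tracking motion estimation,
   motion compensation, Kalman-gated track linking (constant-velocity state,
   optimal bipartite assignment, 278 µm gate, ≥ 3 consecutive frames),
   super-resolution track-map rendering (count / direction / speed),
   flow-direction artery/vein separation and track statistics.
3. **`srusval.coreg`** — similarity transform (rotation + isotropic scale +
   translation) between the 2D imaging slab and the 3D volume: closed-form
   least-squares landmark fitting, inversion, slab maximum-intensity
   projections, and 3D→2D centerline projection with elevation gating.
4. **`srusval.metrics`** — the quantitative comparison: centerline dilation
   into ROI masks, centerline/track-map overlap percentages with a
   mirrored-ROI null control, skeleton centerline extraction, the 4-s.d.
   diameter proxy, line intensity profiles with −3 dB peak widths, and
   counting of superposed vessel bundles through the elevation slab.
5. **`srusval.pipeline` / `srusval.cli`** — orchestration with config files,
   run manifests (seeds, checksums) and a JSON/CSV report.

## CLI

```sh
# full experiment: phantom -> frames/CT -> ULM -> co-registration -> metrics
srusval run --out runs/demo --seed 1
srusval run --config config.yaml --out runs/demo --max-link-um 278 --min-frames 3

# individual stages
srusval synth --seed 1 --out runs/synth
srusval ulm run --frames runs/synth/frames.tiff --out runs/ulm
srusval coreg fit-landmarks --landmarks landmarks.csv --out transform.json
srusval coreg mip --volume ct.nii.gz --transform transform.json --out mip.tiff
srusval coreg project --centerlines cls.json --transform transform.json --out proj.json
srusval metrics overlap --centerlines srus_cls.json --roi-centerlines ct_cls.json --dilation-mm 0.3
srusval metrics mirror-control --trackmap runs/demo/trackmap_vein.tiff \
    --roi-centerlines ct_cls.json --dilation-mm 0.3
srusval metrics profile --image mip.tiff --p0 2.0 1.0 --p1 2.0 6.0
srusval metrics bundles --centerlines cls.json --transform transform.json --pixel 5.0 5.0
```

A config file is plain YAML mirroring `srusval.pipeline.RunConfig`; CLI
flags override it, and every run writes a manifest with the config
snapshot, seeds and per-stage checksums.

## Conventions

- Physical units are millimetres; rasters are indexed `[row=axial/depth,
  col=lateral]` with pixel/voxel centers at `origin + (index + 0.5) * spacing`.
- Flow direction angles: 0° = +lateral, counter-clockwise, range (−180°, 180°].
- Slab membership is half-open: `−thickness/2 ≤ elevation < thickness/2`.
- File interchange is text-friendly: multi-page TIFF + JSON sidecars for
  frames/maps, NIfTI or TIFF for volumes, CSV for events/tracks/landmarks,
  JSON for phantoms, transforms and centerlines. Missing pixel-size or
  spacing metadata is a hard error — nothing is guessed.

## Acceptance

`tests/test_acceptance.py` holds the acceptance criteria (gate invariants,
tracker–oracle equivalence, localization/motion accuracy, similarity-fit
exactness, diameter and −3 dB estimators against closed forms, the
end-to-end phantom benchmark with its mirrored-ROI control, the
superposition counter and CT rasterization geometry).

The acceptance report is produced by

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which runs a small end-to-end pipeline as a sanity gate and writes the
target map (empty: the comparison study this emulates deposits no raw
data, so there are no numeric targets to recompute; acceptance is
property-based).
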