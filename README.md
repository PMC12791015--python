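# nanolabel

Detection, randomization and quantification of nanogold labels in
cryo-electron tomograms, exercised end-to-end on a synthetic tomogram
generator with known ground truth.

The pipeline covers:

* **core_io** — domain types (`VolumeGrid`, `ParticleTable`,
  `GoldDetection`, …) and readers/writers for MRC2014 volumes and
  STAR/CSV particle tables. All internal geometry is in Å; voxel centers
  sit at `(i + 0.5) * voxel_size + origin`; orientations are intrinsic
  ZYZ `(rot, tilt, psi)` degrees; contrast (`density_dark` vs
  `density_bright`) is an explicit field and is never flipped implicitly.
* **simulate** — synthetic tomograms: globular particles at random
  positions/orientations, gold spheres tethered at a truncated-Gaussian
  distance from a tag site fixed in the particle frame, a configurable
  unbound-gold count, and additive white noise — plus the emitted ground
  truth (`simulate_truth` draws coordinates only; `simulate_tomogram`
  also rasterizes).
* **detect** — whole-tomogram gold detection: slab averaging along z,
  [0, 1] normalization, thresholding at `mean + k_sd * SD` (default 3.3),
  connected components (6/18/26), singleton removal, voxel-count gating
  (defaults 40–55 for 1.4-nm gold on a 3 Å grid, where the theoretical
  sphere volume is 53 voxels), and centroid extraction.
* **randomize** — per-subtomogram replacement of supra-threshold voxels
  by draws within one SD of the subtomogram mean, so alignment is driven
  by the macromolecule rather than the gold.
* **geometry** — tag-site re-centering, minimum site-to-gold distances,
  worm-like-chain tether bound, bound/unbound classification,
  labeling efficiency `n_labeled / (n_labeled + n_unlabeled)`, and
  distance-distribution summaries.
* **quantify** — fluorescence calibration regression, Avogadro
  conversion, subvolume-to-cell copy-number extrapolation, and gold
  size-distribution statistics with a two-group separability flag.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: printed-number
reproduction (labeling efficiency, theoretical voxel count, pixel span)
and property-based oracles (detection precision/recall on simulated
volumes, efficiency and distance recovery, the randomization contract,
and geometry brute-force checks).

## CLI

```sh
nanolabel simulate  --config cfg.yaml --out-volume vol.mrc --out-truth truth.csv
nanolabel detect    --volume vol.mrc --params params.yaml --out detections.csv
nanolabel randomize --stack-dir boxes/ --out-dir randomized/ --k-sd 3.3 --seed 1
nanolabel distances --sites sites.csv --golds detections.csv --cutoff-nm 10 --out summary.json
nanolabel quantify  calibrate|invert|extrapolate|sizes ...
```

`simulate` reads a YAML `SimulationConfig`; `detect` a YAML
`DetectionParams`. Raw tomograms are assumed `density_dark` and are
inverted before thresholding unless `--density-bright` is passed.
Detections CSVs have columns
`component_id,x_A,y_A,z_A,voxel_count,peak_intensity`.

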