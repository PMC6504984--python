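# meshfidelity

How accurately do threshold-segmented CT-derived triangular meshes reproduce a
reference-scanned dental stone model?

`meshfidelity` implements the full measurement pipeline as a tested Python
package:

- **phantom** — synthetic dental-arch phantoms (watertight ground-truth
  surface) and a CT-like forward model per scanner preset: partial-volume
  occupancy, Gaussian blur, noise, affine HU calibration; DICOM series I/O.
- **meshing** — iso-surface extraction at a sweep of HU threshold levels
  (default 1425–2625 in 100-unit steps, 13 segmentations), simultaneous
  cropping, STL (binary/ASCII) I/O.
- **registration** — two-stage rigid alignment: coarse correspondence-point
  Kabsch fit, then ICP on sampled point pairs, plus a clone–perturb–register
  software self-accuracy test.
- **metrics** — per-face absolute deviations (exact closest-point queries
  against the reference surface) and their summary statistics: median, IQR,
  the Dissimilarity Index `DI = median × IQR × 1000`, the 95% bound, mean, SD.
- **sweep** — per-case orchestration (extract → group-register → crop →
  register-to-reference → summarise) with best-threshold selection by minimum
  DI, and study-level descriptive tables.
- **stats_inference** — one- and two-way repeated-measures ANOVA with
  Greenhouse–Geisser correction, Dunn–Šidák-corrected pairwise comparisons,
  simple main effects, repeated-scan repeatability.
- **cli_io / cli** — YAML-configured study runner, run manifests, and a
  packaged 30-row reference results table (10 cases × 3 scanning modalities)
  for offline table-level verification.

## CLI

```bash
meshfidelity --version
meshfidelity phantom  --spec spec.json --out phantom_out/
meshfidelity segment  --dicom phantom_out/NewtomVG --levels 1425:2625:100 --out meshes/
meshfidelity register --fixed ref.stl --moving test.stl --pairs 50000 --seed 7 --out transform.json
meshfidelity sweep    --config study.yaml --out results/      # table2.csv, table4.csv, sweep_long.csv
meshfidelity stats    --table results/table2.csv --dv median --out stats/
meshfidelity reproduce-tables                                  # verify packaged reference table
```

A minimal study config:

```yaml
seed: 1
cases:
  - {case_id: case01, n_teeth: 4, arch_radius_mm: 6.0,
     tooth_height_mm: 3.0, gingiva_band_mm: 4.0, surface_resolution_mm: 0.25}
devices:
  - {preset: NewtomVG, voxel_mm: 0.4}
  - {preset: Planmeca80, voxel_mm: 0.4}
sweep: {}          # default 13 levels, 1425:2625:100
crop: auto         # box keeping teeth + a 3 mm gingiva band
icp: {n_sample_pairs: 2000, max_iterations: 15}
```

Every `sweep`/`phantom` run writes a `manifest.json` (config hash, seed,
package versions) sufficient to re-run bit-identically; two runs with the
same config produce byte-identical CSV outputs.

## Conventions

- Common mm frame for meshes and volumes; a volume's origin is its lower
  corner, voxel centers at `origin + (i + 1/2) * spacing`.
- Quantiles use linear interpolation between order statistics.
- Deviations are unsigned, measured from each test-face centroid to its exact
  closest point on the reference surface.
- Best-threshold ties break toward the lower HU level.
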