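# txmquant

Quantification of metal-nanoparticle cluster uptake in cells from
transmission X-ray microscopy (TXM), with a full synthetic test bench:
cell-phantom generation, absorption-contrast projection, limited-angle
tomographic reconstruction, grey-value cluster segmentation, moment-based
size estimation, and per-cell uptake statistics.

## The problem

Full-field TXM at 8 keV resolves ~30 nm detail over a ~24 µm field of view,
enough to image gold-nanoparticle (AuNP) clusters inside whole cells without
sectioning. Quantifying uptake from such images means answering, per cell:

* **how many** clusters were internalized,
* **how large** each cluster is, summarized by a per-cell size distribution
  and its peak (mode),
* **where** clusters sit relative to the nucleus (AuNPs do not cross the
  nuclear envelope; in some cell lines they concentrate in a thin
  perinuclear shell ~1 ± 0.5 µm outside it),
* and how 2D projection measurements **differ from** true 3D tomographic
  measurements of the same specimen.

`txmquant` implements this workflow as a reproducible pipeline and, because
raw micrographs of this kind are rarely deposited, ships a first-class
synthetic-data module so every stage can be validated against ground truth.

## Method summary

**Scene.** A phantom is a labeled voxel volume — ellipsoidal cell, ellipsoidal
nucleus, and *n* voxel-disjoint gold-dense ellipsoidal clusters placed either
uniformly in the cytoplasm or in a perinuclear shell; the nucleus excludes
clusters by construction. Cluster sizes are log-normal
(`S = exp(µ + σZ)`, mode `exp(µ − σ²)`). Attenuation at 8 keV: gold
≈ 0.4 µm⁻¹, soft tissue ≈ 0.001 µm⁻¹.

**Imaging.** Parallel-beam Beer–Lambert transmission
`T(θ) = exp(−∫ µ dl)` along rays at 1° steps, optionally Poisson photon
noise and a Gaussian PSF; flat-field normalization `I/I₀` and mosaic
patchworking mirror the acquisition. Reconstruction is slice-wise filtered
back-projection (ramp filter, optional Hann apodization) over exactly the
acquired angles; a 140° span (the instrument's mechanical limit) leaves a
missing wedge that the package reports rather than in-paints.

**Quantification.** A grey threshold (Otsu's rule on the within-cell grey
values, manually overridable) segments clusters; connected components
(8-connectivity in 2D, 26 in 3D) are each fitted by the ellipse/ellipsoid
with the same second central moments, and the scalar cluster size is the
arithmetic mean of the fitted full axes. Clusters are kept only if they
clearly reside inside the cell (centroid inside and ≥ 90% of voxels inside);
each surviving cluster gets a signed centroid-to-nuclear-surface distance.

**Statistics.** Per-cell and pooled size histograms (20 nm bins, 0–800 nm),
KDE mode estimates (Silverman bandwidth), and two-sample Kolmogorov–Smirnov
comparisons between whole size distributions, including the 2D-vs-3D
contrast.

## Worked example

```python
from txmquant import PhantomConfig, RunConfig, run_pipeline
from txmquant.pipeline import OpticsConfig

config = RunConfig(
    phantom=PhantomConfig(
        shape=(96, 96, 96), voxel_pitch_nm=15.0,
        cell_axes_nm=(650.0, 650.0, 600.0),
        nucleus_axes_nm=(200.0, 200.0, 180.0),
        n_clusters=25, size_median_nm=158.0, size_log_sigma=0.35,
        min_size_nm=60.0),
    optics=OpticsConfig(angle_start_deg=0, angle_stop_deg=140, angle_step_deg=1),
    cell_id="demo_cell", seed=7,
)
result = run_pipeline(config, "demo_run")
```

prints, via the artifacts it writes:

```
planted clusters : 25
3D detections    : 23
2D detections    : 8 (single 0-degree projection)
grey threshold   : 0.182 /um (Otsu)
nucleus distance : 265 +/- 79 nm, fraction inside nucleus = 0
3D size mode     : 169 nm
```

Reading: of 25 planted clusters the 140°-limited-angle tomogram recovers 23
(two merge/miss under the missing-wedge blur), a single 2D projection finds
only 8 (clusters overlap along the beam — the 2D-vs-3D bias this package
measures), no cluster is ever localized inside the nucleus, and the fitted
size mode (169 nm) sits near the generator's distribution peak (140 nm) for
a 23-cluster sample. `demo_run/` now holds the phantom stacks + truth CSV,
the projection series, the reconstruction, `clusters.csv` (per-cluster
measurements, 2D and 3D tagged), `uptake_report.csv`, and QC/manifest YAML.

The same pipeline is available from the shell:

```bash
txmquant run --preset emt-like --seed 7 --out-dir runs/emt
txmquant quantify image.tif --pixel-pitch 15 --out-dir out/   # your own TIFF
```

Presets: `emt-like` (large clusters, size peak ~140 nm, uniform in
cytoplasm) and `hela-like` (small clusters, peak ~30 nm, perinuclear shell
0.5–1.5 µm).

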