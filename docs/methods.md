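# Methods

This note documents the models, conventions, parameters, and design choices
behind `txmquant`, and what the synthetic test bench does and does not
demonstrate about real transmission X-ray microscopy (TXM) data.

## Scene model (phantom module)

A phantom is one cell: an axis-aligned ellipsoidal cell containing an
axis-aligned ellipsoidal nucleus (validated to lie strictly inside the cell
by sampling its surface), plus `n` nanoparticle clusters. Clusters are
homogeneous gold-dense ellipsoids with mild random axis anisotropy (axis
factors uniform in ±15%, renormalized so the axis mean equals the drawn
size) and uniformly random orientation. The label volume uses 0 =
background, 1 = cytoplasm, 2 = nucleus, ids ≥ 3 = clusters; coordinates are
(z, y, x) voxel indices with physical position `(index + 0.5) × pitch` nm.

**Voxel pitch** defaults to 15 nm — half the instrument's 30 nm lateral
resolution — so resolution-limited clusters span at least two voxels
(Nyquist).

**Size distribution** is log-normal: positive support and a single mode,
matching the unimodal per-cell histograms this kind of experiment reports.
The presets are parameterized by the distribution *peak* (mode), the
statistic the experiments quote: the median is `mode × exp(σ²)`. Both
presets use σ = 0.35, a spread consistent with the visual width of published
per-cell histograms; an optional lower truncation (by resampling) models the
detectability floor. Other families can be plugged in behind the same
sampling interface.

**Placement** is rejection sampling: a candidate centroid is drawn uniformly
over the cell bounding box and accepted only if the rendered cluster lies
entirely in the cytoplasm (never touching the nucleus — the nuclear envelope
excludes particles, and the generator enforces this exactly), and keeps a
minimum surface-to-surface separation of 60 nm (two resolution elements)
from every earlier cluster so the ground-truth catalog stays unambiguous
after reconstruction blur. In `perinuclear_shell` mode the centroid's signed
nuclear-surface distance must additionally fall in the configured
[inner, outer] band. After 1000 failed attempts for one cluster a
`PlacementError` names the shortfall. The truth catalog records the
*voxelized* geometry — centroid, moment-ellipsoid axes, and nuclear distance
of the rendered component — measured with exactly the conventions the
quantification stage uses, so end-to-end comparisons are not confounded by
rendering quantization.

**Attenuation** defaults (8 keV linear coefficients) come from standard
mass-attenuation tables: bulk gold ≈ 0.4 µm⁻¹, soft tissue/water
≈ 0.001 µm⁻¹, nucleus 0.0015 µm⁻¹ (slightly denser). They are scene
parameters, not fitted claims; clusters are modeled as homogeneous
gold-dense solids because the sub-resolution packing of ~15 nm primary
particles inside a cluster is not observable at this scale.

## Imaging model (optics module)

Parallel-beam Beer–Lambert absorption contrast: each frame pixel is
`exp(−L(θ))` with `L` the line integral of attenuation (µm⁻¹ × µm) along the
ray. Parallel geometry is a good approximation for a zone-plate full-field
microscope with a 24 µm field of view. The rotation axis is the volume z
axis; at θ = 0 rays run along +x. Integration is slice-wise rotation
(bilinear) plus axis summation; the internal rotation angle carries a +90°
offset so that the 0° ray direction is along +x while staying consistent
with the slice-wise filtered back-projection inverse (verified by
point-source localization tests). Content outside the slice's inscribed
circle is cropped by the rotating grid, so phantoms are kept inside it.

Optional stages: Poisson photon noise (`Poisson(N·T)/N` for background count
N, seeded), a Gaussian PSF of configurable FWHM (default 30 nm, off in
oracle tests), flat-field normalization (elementwise `raw/flat`, erroring on
non-positive flat pixels), and mosaic patchworking (overlaps averaged, gaps
warned with pixel counts).

## Reconstruction (recon module)

Transmission frames are clamped at a 1e-8 floor (clamp count logged),
−log-transformed, and reordered to per-slice sinograms. Each slice is
reconstructed by filtered back-projection with a ramp filter over exactly
the acquired angles — no angular in-painting; the missing wedge of a 140°
scan shows up as anisotropic blur, which is the physically honest behavior.
Hann apodization is applied automatically for noisy data and off otherwise.
Negative reconstructed values are retained; clamping them would bias the
downstream threshold. The coverage report flags `limited_angle` when the
angular span plus one mean step falls short of 180° (so a 0–179° scan at 1°
steps counts as full coverage). The rotation axis is assumed centered and
aligned — true for synthetic data; real data would need registration first.

## Quantification (quant module)

**Thresholding.** Interactive grey-value selection is replaced by Otsu's
between-class-variance rule (256 bins), with a manual override. When a cell
mask is available the histogram is restricted to within-cell grey values:
the threshold must separate clusters from tissue, not the cell silhouette
from the background. A class-separation guard rejects auto-thresholds whose
two classes are separated by less than 6 background-class standard
deviations: an Otsu split of a cluster-free (unimodal) grey distribution
reaches only ~2–4, while genuine gold/tissue contrast measures ≥ 8 across
scene types, so a failed guard means "no cluster grey-value class present"
and zero clusters are reported (with a QC flag) instead of segmenting the
nucleus or half the cytoplasm as one giant component. The guard does not
apply to manual thresholds.

**Segmentation.** Connected components of the thresholded mask under full
connectivity (8 in 2D, 26 in 3D; recorded in QC). Clusters are dark in
transmission frames and bright in attenuation volumes — the polarity is
explicit. Components under 2 pixels/voxels are below the resolution floor;
they are excluded from distributions but counted in QC. Touching clusters
are deliberately *not* watershed-split: merged aggregates count as single
clusters.

**Sizing.** Each component is summarized by the ellipse/ellipsoid sharing
its second central moments. The discrete covariance adds 1/12 per axis for
the unit-pixel footprint (this makes a 1×N pixel line measure
`N·pitch·2/√3` exactly). Full axes are `4√λ` in 2D (solid ellipse:
second moment a²/4) and `2√(5λ)` in 3D (solid ellipsoid: a²/5). The scalar
size is the arithmetic mean of the axes — of 2 axes for projection images,
of 3 for tomograms — and every record carries a 2D/3D dimensionality tag so
the two are never silently mixed. Degenerate (coplanar) components have
their smallest axis floored at one voxel pitch and flagged.

**Containment and localization.** "Clearly inside the cell" is
operationalized as centroid-in-mask AND ≥ 90% of component voxels in-mask
(fraction configurable); rejections are counted. Nuclear distances are
signed (positive outside), computed from the difference of two Euclidean
distance transforms of the nucleus mask sampled with linear interpolation at
the cluster centroid — accurate to about one voxel pitch, limited by surface
discretization. An empty nucleus mask yields NaN distances with a flag, not
zeros.

## Statistics (stats module)

Histograms default to 20 nm bins over 0–800 nm; out-of-range sizes go to an
overflow counter rather than being dropped. Modes are estimated by Gaussian
KDE (Silverman bandwidth) maximized on a dense grid, with ties broken toward
the smaller size; below n = 5 a tallest-bin fallback is used and flagged.
Histogram-bin modes are also emitted, since KDE and bin modes can differ.
Distribution comparisons use the two-sample Kolmogorov–Smirnov test —
chosen because whole size distributions, not just means, are being compared
— with the exact small-sample p-value for n ≤ 100 per sample (flagged) and
the asymptotic one above. The per-cell uptake report lists cluster count,
size mean/SD/mode, nuclear-distance mean/SD, and the fraction of clusters
inside the nucleus (expected 0), with a pooled row appended; per-cell and
pooled views are both emitted because published histograms are ambiguous
about pooling.

## Pipeline, presets, and scale

One global seed drives every stochastic stage through spawned child seeds;
identical configs give byte-identical catalogs. Artifacts are multi-page
TIFF (32-bit float volumes, 16-bit labels), YAML sidecars/QC/manifest, and
CSV catalogs, all in nm.

The presets emulate the two observed uptake phenotypes: `emt-like` — 120
clusters, size peak 140 nm, uniform in cytoplasm; `hela-like` — 80 clusters,
size peak 30 nm, perinuclear shell 0.5–1.5 µm outside the nuclear envelope.
Phantom cells are miniaturized (~3–3.5 µm across rather than ~15–20 µm): a
full-scale cell at 15 nm pitch would need a ~2048³ grid, which buys nothing
scientifically for validating the measurement chain. Consequences worth
knowing:

* cluster density per projected area is higher than in a real cell, so the
  2D-vs-3D merging bias is, if anything, stronger in the synthetic scenes;
* the `hela-like` cell radius truncates the reachable part of the 0.5–1.5 µm
  shell (to ≈ 1.15 µm), pulling the recovered mean perinuclear distance to
  ~0.9 µm instead of 1.0 µm;
* 30 nm clusters span only two voxels, and the moment size of a 2–3 voxel
  component floors near ~39 nm, so the recovered `hela-like` size mode reads
  high (~45 nm). This is the instrument's resolution floor reproduced
  faithfully; the package reports the bias rather than correcting it.

Problem sizes used by the test suite and the acceptance script — 256³ for
the end-to-end recovery check, 192³/224³ for the presets, 128³ for
tomographic fidelity, 64³ for the 20-seed bias study — were chosen as the
smallest scenes that keep every cluster ≥ 2 voxels and the cytoplasm several
cluster diameters deep.

## What passing tests do and do not show

The synthetic bench validates the measurement chain: geometry, projection
physics, reconstruction fidelity, segmentation correctness against
brute-force oracles, sizing against closed forms, and preservation of the
nucleus-exclusion invariant end-to-end. It does **not** emulate: phase
contrast (the qualitative Zernike mode of the instrument), staining
chemistry, detector blur beyond a Gaussian PSF, projection misalignment,
multi-cell fields, scaffold geometry, or sub-cluster particle packing. Real
images additionally need registration and may violate the parallel-beam and
aligned-rotation-axis assumptions; results on real TIFFs should be read with
the QC output (threshold source, class separation, rejection counts) in
hand.

## Numerical notes

* Angles are degrees; frames are dimensionless transmission in (0, 1] for
  noiseless data (noise can push pixels past 1).
* FBP output units are µm⁻¹ (sinograms are divided by the pixel pitch in µm
  before inversion).
* Otsu plateaus: with an empty histogram valley, any split inside the valley
  maximizes between-class variance; tests therefore compare achieved
  variance, not threshold location.
* The KS null-rejection calibration uses n = 100 per sample with the exact
  method; observed rejection at α = 0.05 is ~4% over 1000 replicates.
* Ties in mode estimation break toward the smaller size (first maximum on
  an ascending grid).
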