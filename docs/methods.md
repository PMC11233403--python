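# Methods

`glycovol` estimates the volumetric content of glycogen granules in skeletal
muscle from 2-D electron micrographs of ultrathin (~60 nm) sections. The
pipeline has four stages: per-pixel semantic segmentation, per-region pixel
fraction statistics, a stereological calibration converting pixel fraction to
volume fraction and granule concentration, and cluster-corrected group
comparison. This note records the models, the defaults that matter, and the
numerical choices made where the design was open.

## Pixel fractions

Given a *Locations* mask (labels 0 unclassified, 1 A band, 2 I band,
3 mitochondria/Z disk, 4 SR, 5 near-SR intermyofibrillar cytosol) and a
binary *Granules* mask on the same raster, the pixel fraction of region R is

    pf_R = n_R / N_R

with `n_R` granule pixels and `N_R` total pixels carrying label R.
Unclassified pixels are excluded from every numerator and denominator — a
granule pixel sitting on label 0 is counted nowhere — and the whole-cell
fraction pools labels 1–5. A granule straddling a region boundary is split
pixel-wise between the regions. Regions with `N_R = 0` report `pf_R` as
missing (NaN), not zero. Sampled volume per region is
`N_R × pixel_nm² × t`, with section thickness `t = 60 nm` by default
(sections are cut at 50–70 nm; `t` is a config knob).

## Stereological calibration (basket simulation)

A section image reports a 2-D quantity; the target quantities are 3-D: the
volume fraction `vf` occupied by granules and their concentration `G`
(granules/µm³). The mapping pf → vf is nonlinear because granules overlap in
projection and are severed by the section cuts. It is calibrated by a
Boolean-model simulation:

- **Basket**: 400 × 400 × 200 voxels representing a 1,000 × 1,000 × 500 nm
  half-cube (volume 0.5 µm³). The effective voxel pitch is therefore
  2.5 nm: 400 voxels span the 1,000 nm side and a 24-voxel slab spans the
  60 nm section. Area/volume bookkeeping uses this pitch throughout; with a
  2.0 nm pitch the stated basket volume, concentration range, and slab
  thickness would all be mutually inconsistent.
- **Granules**: spheres with diameters drawn from a truncated normal —
  mean 25 nm ("Small") or 27.5 nm ("Large"), SD 5 nm, truncated below
  5 nm (a N(25, 5) draw essentially never goes lower; the floor guards
  against nonphysical radii). Centers are uniform over the grid, overlaps
  allowed, spheres clipped at the faces (no periodic wrap).
- **Voxelization**: a voxel is occupied iff its center lies inside any
  sphere — unbiased and trivially checkable against an exhaustive oracle.
  `vf` is the occupied fraction of the whole basket.
- **Sectioning**: slabs of 24 voxels (60 nm) starting 12 voxels above the
  bottom face to avoid border effects; a 200-voxel-deep basket yields
  exactly 7 slabs. Each slab is projected onto x–y (pixel = 1 iff any voxel
  in its column is occupied), mimicking the binary output of the granules
  segmenter; the basket's `pf` is the unweighted mean over the 7 slab
  projections.
- **Design points**: 8 granule counts linearly spaced 400…3,000 (i.e.
  `G` = 800…6,000 µm⁻³, covering the observed range), for each of the two
  diameter distributions — 16 (pf, vf, G) points per run.
- **Fits**: unweighted least-squares quadratics `vf(pf)` per distribution
  and pooled, and `G(pf)` per distribution.

Low-density correctness is checked against the Boolean-model closed form
`vf = 1 − exp(−G·E[V])`, `E[V] = (π/6)(µ³ + 3µσ²)`.

On 8 points the quadratic coefficients a and b trade off strongly, so a
single run leaves visible sampling noise in both. Where a stable coefficient
estimate is wanted (the acceptance script, the calibration regression test)
the full 8-basket protocol is repeated 6 times with independent seeds and
coefficients are averaged; this changes the variance of the estimator, not
the estimand. The key scientific property — `vf(pf)` nearly insensitive to
granule size while `G(pf)` is not — is asserted as <10% relative difference
between the Small and Large `vf(pf)` curves over their shared pf range.

The default conversion polynomial shipped in `concentration` is the pooled
fit `vf = 0.1511·pf² + 0.2344·pf + 0.0005`, with the per-distribution
`G(pf)` quadratics (17571/26253/8 and 13940/20667/8) bracketing the granule
concentration. `simulate-calibration` regenerates a package-fitted set; the
pooled quadratic term it produces is noisy and can differ visibly from the
shipped constant, which is reported rather than forced to agree.

## Glycogen concentration

The reference granule holds 55,000 glycosyl residues at 167 Da/residue in a
sphere of radius 21 nm, giving a density of ≈393 g of glycogen per liter of
granule. Multiplying by `vf` gives g/l of cell; discounting a 9%
extracellular volume fraction gives g/l of muscle tissue (coefficient
393 × 0.91 ≈ 358, computed rather than hard-coded). Avogadro's number
defaults to 6.023 × 10²³ to reproduce the 393 figure exactly as derived;
`GranulePhysParams(avogadro=AVOGADRO_CODATA)` switches to the CODATA value.
Whole-cell results are computed from pooled pixel counts, never by averaging
regional results.

## Granule morphometry

Connected components of the binary granules mask (8-connectivity) each yield
one outer contour; holes are ignored because granules are solid. Contours
are traced by marching squares at level 0.5 and snapped to the boundary
*pixel centers*, so a digital disk of radius r px measures 2r px across and
a 10 × 10 px square measures a 9√2 px diagonal. The granule length is the
Feret diameter — the maximum pairwise distance among contour points —
computed on the convex hull for speed, with the O(n²) brute force retained
as the test oracle. Overlapping granules merge into one silhouette and
produce spuriously long lengths; the diameter distribution is therefore read
from lengths below a 50 nm cutoff, binned at 2.5 nm (resolving the 15–40 nm
granule range).

## Segmenters

Two UNet-type models share one implementation: *Locations* (6 classes) and
*Granules* (2 classes; only the final 1 × 1 classification layer differs).
The encoder halves the spatial side and doubles the channel count per level;
the decoder mirrors it with nearest-neighbor upsampling and skip
concatenation; training minimizes per-pixel cross entropy (optional class
weights for the rare granule class) and alternates between Adam and Nadam
every 10 epochs (configurable), sharing moment state across the switch.
Augmentation applies identical 90° rotations/mirroring to image and mask and
contrast changes to the image alone. Accuracy is the fraction of correctly
classified pixels, counting label 0 unless explicitly ignored.

The network is implemented directly on numpy (im2col convolutions,
max-pooling, nearest upsampling, hand-derived backward passes): the exact
layer inventory of the original study is not published, and its published
accuracies depend on its training images, so nothing here gates on them.
Defaults (depth 3, 8 base channels, 256² inputs, learning rate 3 × 10⁻³)
train in about one second per epoch per image on one CPU; capacity is
verified by memorizing two synthetic scenes to ≥95% training pixel accuracy
— above the all-background baseline, with granule recall checked so the
model demonstrably finds granules rather than the majority class.

## Synthetic scenes

The fixture generator emulates the features the pipeline consumes: axial
band stripes (period ordered A | SR | near-SR | I/2 | Z | I/2 | near-SR |
SR), per-region background gray levels (I band lightest, Z/mito darkest),
dark granule disks with truncated-normal diameters, per-region target areal
fractions (disks placed uniformly within the region, overlap allowed, with
an attempt cap that raises once a target is unreachable), and additive
Gaussian noise clipped to 8 bits. The sarcomere period defaults to 120 nm —
compressed roughly 17-fold against real sarcomeres so a 256² crop at 0.8
nm/pixel shows several periods. Consequences: granule disks are wider than
the thin SR stripes, so realized per-region fractions mix the seeded
densities with cross-boundary spillover, and no claim about *relative*
region densities in real tissue can be read off fixtures. What passing
tests show is the correctness of counting, geometry, and learning capacity —
not EM realism: there is no texture, no staining artifacts, no SR-bound
glycogen layer, and no filament-aligned granule ordering.

A separate helper lays strictly non-touching disks on a jittered grid for
morphometric validation, where merged silhouettes would confound diameter
recovery.

## Hierarchical statistics

Image-level values cluster within subjects. The comparison of two groups
uses the design-effect correction: one-way ANOVA ICC
`(MSB − MSW)/(MSB + (m̄ − 1)·MSW)` (m̄ = arithmetic mean cluster size,
estimates floored at 0; when pooling the two groups the values are centered
by group mean and the between-cluster mean square uses k − 2 degrees of
freedom, k the total cluster count), naive pooled-t SE inflated by
`√(1 + (m̄ − 1)·ICC)`, and a t reference with k − 2 df — deliberately
conservative. With ICC = 0 or one image per cluster the procedure reduces
exactly to the ordinary two-sample t-test. Under a strongly clustered null
(σ_between = σ_within, 7 clusters × 60 images per group) the corrected test
holds its size near 5% in simulation while the naive test rejects at >30%.
The clinical-index association is an equal-weighted Pearson correlation of
image-level values against the subject's index.

## Known limitations

- The pf → vf polynomial assumes spatially random granule placement;
  filament-aligned granules in I bands violate this mildly at low fractions.
- Measured diameters are biased low by cap sections (a small silhouette may
  be a polar cap of a large granule); no iterative correction is applied.
- The segmenters are desk-scale: they verify learnability and the training
  regime, not field accuracy on real micrographs.
- Predicted-mask cleanup before counting is deliberately absent: boundary
  oscillations in predictions largely cancel in pixel-fraction sums.
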