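# Methods

`tubulemorph` quantifies microtubule (MT) bundling in pollen tubes from two
kinds of data: single-molecule localization microscopy (dSTORM) localization
tables, from which it measures per-tubule width, length and intensity, and
two-channel confocal z-stacks, from which it computes Manders colocalization
coefficients and ROI percent-volume / mean-intensity readouts.  A
ground-truthed simulator backs every stage, so the whole pipeline is testable
without experimental data.

## SMLM morphometry pipeline

1. **Reconstruction.** A localization table (nm coordinates) is rendered as a
   2D count histogram with half-open square pixels,
   `index = floor(coord / pixel_size)`.  The default pixel size is 20 nm,
   matching the effective resolution of dSTORM.  The sum of pixel counts
   equals the number of in-extent localizations by construction.

2. **Segmentation.** Elongated structures are enhanced with the multi-scale
   Frangi vesselness measure.  At each scale `sigma` the Hessian is computed
   with separable Gaussian-derivative filters (reflective boundaries,
   kernels truncated at 8 sigma so flat regions give numerically zero
   curvature) and gamma-normalized by `sigma^2`.  With eigenvalues ordered
   `|l1| <= |l2|`, blobness `Rb = l1/l2` and structureness
   `S = sqrt(l1^2 + l2^2)`:

       V = 0                                               if l2 >= 0
       V = exp(-Rb^2 / 2 beta^2) (1 - exp(-S^2 / 2 c^2))   otherwise

   taking the maximum over scales.  Bright-on-dark polarity (`l2 < 0`) is
   hard-coded because STORM reconstructions are bright on dark.  A single
   global threshold (Otsu by default) converts vesselness into the binary
   tubule mask.

3. **Skeleton and branches.** The mask is thinned to a unit-width,
   8-connected skeleton.  Pixels with more than two skeleton neighbors are
   junctions; removing them leaves maximal junction-free chains, each an
   ordered branch (closed chains are flagged as cycles and excluded from
   measurement).

4. **Straight-branch selection.** Straightness = Euclidean endpoint distance
   divided by the diagonal-aware path length (cardinal steps 1, diagonal
   steps sqrt(2)).  The selection cutoff is 0.92: an ideal 8-connected
   straight line has chord/path as low as 0.9237 near 22.5 deg (the naive
   chain-length bias), while a quarter-circle arc scores ~0.86-0.90, so 0.92
   separates digitally-straight from genuinely bent without penalizing
   oblique tubules.  Branches shorter than 5 px are discarded.

5. **Rotation and measurement.** For each selected branch, localizations in
   a padded window are rigidly rotated about the branch centroid so the
   tubule aligns with the pixel grid -- rotation always acts on the
   continuous localization list, never on a rendered image, so no
   interpolation enters the width estimate.  The alignment angle comes from
   the branch's principal axis and is refined once from the principal axis
   of the re-segmented component (a short skeleton fragment can misestimate
   the angle by >10 deg; the component covers far more pixels).  The window
   is re-rendered at the measurement pixel size (20 nm by default; 5 nm for
   sub-pixel width work) and re-segmented with the *same physical filter*:
   sigmas are defined on the reconstruction grid and are rescaled by the
   pixel-size ratio when the measurement grid is finer.  On the connected
   component overlapping the rotated branch:

   * width = median over occupied columns of the transverse pixel run,
     times the pixel size;
   * length = number of occupied columns, times the pixel size;
   * intensity = localization count inside the component (total and
     per-pixel mean are both reported).

   Components shorter than the minimum branch length (in physical units)
   are dropped: they sample too few emitters for the per-column statistic
   to mean anything.  Components touching the window border are flagged;
   their length is a lower bound.

6. **Statistics.** Width and intensity distributions are compared between
   conditions with the Kruskal-Wallis rank test (mid-ranks, standard tie
   correction).  The p-value uses the chi-square approximation for the
   sample sizes this pipeline produces (hundreds to thousands of tubules);
   for pooled samples of at most 10 values the exact enumerated permutation
   null is used instead, because the chi-square approximation is off by up
   to ~0.2 there.  No multiple-testing correction is applied (single
   pairwise tests per readout).  Histograms use half-open 20 nm bins by
   default, matching the reconstruction pixel.

### What the width readout can and cannot resolve

The width statistic counts mask pixels, so its accuracy is bounded by the
segmentation, which is in turn bounded by the localization supply.  Two
regimes matter:

* **Well-sampled data** (>= ~2 localizations per nm of tubule length, the
  package default): the re-segmented band is contiguous and the readout is
  a strictly monotone, somewhat compressed function of true outer diameter.
  Under the default configuration (20 nm reconstruction, 5 nm measurement)
  simulated diameters 25/50/75/100 nm read approximately 20/30/37/50 nm.
  The compression comes from Otsu cutting the vesselness profile above its
  support: the mask does not reach the dim band edges.  Comparisons between
  conditions (the scientific readout: bundles vs single MTs) are preserved;
  absolute diameters are not.

* **Sparsely-sampled data** (~0.2 localizations/nm): a 5 nm reconstruction
  has of order one localization per pixel column, arriving in per-emitter
  bursts ~20 nm apart.  The vesselness field fragments, and per-column runs
  reflect the filter's own support (~3 px) instead of the tubule: measured
  width becomes *independent of true diameter*.  `scripts/acceptance.py`
  runs exactly this regime for its reported experiment and the resulting
  mean (~14 nm for 25 nm tubules) should be read with that limitation in
  mind; the test suite documents the same behaviour.

Rotation invariance holds to within one measurement pixel at the default
sampling density (the same simulated tubule measured at 0/30/60 deg).

## Confocal quantifications

* **Manders coefficients.**  `M1 = sum(A over voxels with A > tA and
  B > tB) / sum(A over voxels with A > tA)`, `M2` with roles swapped; both
  necessarily in [0, 1].  Thresholds default to 0 (the plain JACoP
  behaviour without auto-thresholding; Costes estimation is out of scope).
  A zero denominator returns NaN with an explicit flag, never a silent 0.
  Sums may be restricted to an axis-aligned ROI box.

* **Percent volume.**  Within an ROI, the "full object" is every voxel
  above a permissive low threshold (the whole tube); the structure volume
  is every voxel above a structure-specific threshold; the readout is
  100 x their ratio.  Invariant under any strictly monotone intensity
  rescaling applied jointly with its thresholds.

* **Mean ROI intensity** over a set of z-planes, defaulting to the five
  planes centred on the medial plane (`ceil(n_z/2)`, 1-based).

* **ROIs** are axis-aligned voxel boxes; micron extents along the tube
  axis convert to voxels via the voxel size, rounding half up.  (The
  original measurements drew manual ROIs; boxes make every number
  deterministic and testable.)

## Synthetic data

`make_tubule_field` draws, in a fixed documented order from one seeded RNG:
Poisson emitter counts (labeling_density x arc length), uniform emitter arc
positions, uniform transverse offsets across the projected cylinder
(+-d/2; antibody geometry is not modelled), Poisson localization counts per
emitter, isotropic Gaussian localization errors, then uniform background.
Bundles are modelled as one tubule of larger outer diameter, matching the
width-only readout.  Defaults: labeling density 0.5 emitters/nm of
centerline with 4 localizations/emitter (2 locs/nm, representative of
immunolabeled dSTORM MT data), localization precision sigma 2 nm, no
background.  The generator does not model photophysics (blinking kinetics,
duty cycle), drift, multi-emitter artifacts, or 3D; passing tests therefore
demonstrate correctness of the analysis on idealized localization
statistics, not robustness to those instrument effects.

`make_confocal_stack` places filament segments inside a cylindrical cell;
a deterministic fraction of channel-A structures (round(f x n), chosen via
a seeded permutation so shared sets nest as f grows on matched seeds) also
appears in channel B, plus optional B-only structures.  Channels are
amplitude x mask, Gaussian-blurred by the PSF and read-noise corrupted.
With zero PSF and zero noise, channel A equals its structure mask exactly
and M1 recovers the generator's shared-voxel fraction to 1e-9.

## Parameter reference

| parameter | default | units | rationale |
|---|---|---|---|
| reconstruction pixel | 20 | nm | dSTORM effective resolution |
| measurement pixel | = reconstruction | nm | 5 nm for sub-pixel width studies |
| Frangi sigmas | 1, 1.5, 2 | px (reconstruction grid) | structures 1-4 px wide |
| beta | 0.5 | - | conventional blobness weight |
| c | half of max S, per scale | intensity | adapts to image contrast |
| threshold | Otsu | - | parameter-free global threshold |
| straightness min | 0.92 | - | keeps ideal digital lines (>= 0.9237), drops arcs (<= 0.90) |
| min branch length | 5 | px | also applied to components, in nm |
| window pad | 10 | px | context for re-segmentation |
| labeling density | 0.5 | emitters/nm | realistic immunolabeling |
| locs per emitter | 4 | - | repeated blinking detections |
| localization precision | 2 | nm | high-quality dSTORM |
| KW p-value | auto | - | exact null for pooled n <= 10, else chi-square |

## Known limitations

* Absolute width is a compressed function of true diameter (see above);
  the pipeline is a *comparative* bundling assay, not a calliper.
* Curved tubules are excluded by design; no arc-length width profiles.
* The intensity readout is a localization count; it tracks label density,
  not protein stoichiometry, and the simulator's bundles carry the same
  linear label density as single MTs.
* Cycles in the skeleton are dropped rather than cut.
* Manders thresholds are manual; Costes auto-thresholding and
  randomization p-values are not implemented.
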