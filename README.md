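# tubulemorph

Morphometry of microtubule bundling from super-resolution and confocal
microscopy of pollen tubes.

Cortical microtubules (MTs) in plant cells associate laterally into bundles;
membrane sterol composition influences how much.  A single MT has a ~25 nm
outer diameter, so telling "single MT" from "bundle" needs either
single-molecule localization microscopy (dSTORM), which yields a list of
fluorophore positions with nanometre precision rather than a pixel image, or
careful 3D quantification of confocal stacks.  `tubulemorph` implements both
readouts as a tested, scriptable pipeline for cell biologists who want to
compare MT bundling between experimental conditions (e.g. control vs
sterol-depleted cells):

* **SMLM morphometry** — render a ThunderSTORM-style localization table as a
  count histogram, enhance elongated structures with the multi-scale Frangi
  vesselness filter, threshold, skeletonize, split the skeleton into
  branches, select straight elements, rotate each tubule's localizations
  into grid alignment, and measure width / length / intensity by pixel
  counting on the re-segmented image.
* **Confocal colocalization and volumes** — Manders coefficients M1/M2 on
  two-channel 3D stacks, percent volume above a structure threshold relative
  to the "full object", and mean intensity over medial planes, all within
  labelled ROI boxes (tip / shank / distal).
* **Statistics** — Kruskal–Wallis comparison of width and intensity
  distributions between conditions, with histogram summaries.
* **Synthetic data** — ground-truthed generators for both data types, so
  every stage can be validated against known truth.

## The core measures

Frangi vesselness at scale $\sigma$, with Hessian eigenvalues
$|\lambda_1| \le |\lambda_2|$, $R_b = \lambda_1/\lambda_2$ and
$S = \sqrt{\lambda_1^2 + \lambda_2^2}$ (bright structures, so
$\lambda_2 < 0$):

$$V_\sigma = \exp\!\left(-\frac{R_b^2}{2\beta^2}\right)\left(1 - \exp\!\left(-\frac{S^2}{2c^2}\right)\right),\qquad V = \max_\sigma V_\sigma$$

Kruskal–Wallis across $k$ groups with rank sums $R_g$:

$$H = \frac{12}{N(N+1)}\sum_g \frac{R_g^2}{n_g} - 3(N+1)$$

with mid-ranks and the standard tie correction; $p$ from $\chi^2_{k-1}$ (an
exact enumerated permutation null is used automatically for pooled
$N \le 10$).

Manders coefficients: $M_1$ is the fraction of channel-A intensity (above
its threshold) lying in voxels where channel B exceeds its threshold, and
symmetrically for $M_2$.

## Worked example

Measure 40 simulated single microtubules against 40 simulated bundles
(50–100 nm) and compare the width distributions:

```python
import numpy as np
from tubulemorph import measure_simulated_tubules, kruskal_wallis

rng = np.random.default_rng(0)
single = measure_simulated_tubules(np.full(40, 25.0), seed=1,
                                   recon_pixel_size=20.0, measure_pixel_size=5.0)
bundle = measure_simulated_tubules(rng.uniform(50, 100, 40), seed=2,
                                   recon_pixel_size=20.0, measure_pixel_size=5.0)
res = kruskal_wallis([single.width_nm, bundle.width_nm])
print(f"single MTs   : n={len(single)}, median width {single.width_nm.median():.1f} nm")
print(f"bundles      : n={len(bundle)}, median width {bundle.width_nm.median():.1f} nm")
print(f"Kruskal-Wallis: H={res.h:.1f}, df={res.df}, p={res.pvalue:.2e}")
```

```
single MTs   : n=40, median width 20.0 nm
bundles      : n=38, median width 40.0 nm
Kruskal-Wallis: H=60.4, df=1, p=7.94e-15
```

Single MTs read ~20 nm and bundles read wider, with an unambiguous
distribution difference.  The width readout is a strictly monotone but
*compressed* function of true diameter (the Otsu-thresholded vesselness
mask does not reach the dim band edges — see `docs/methods.md`), so it
separates conditions reliably while absolute diameters are
resolution-limited.

The same analysis is available from the shell:

```sh
tubulemorph simulate --n-tubules 10 --diameter 25 --out locs.csv
tubulemorph measure locs.csv --pixel-size 20 --measure-pixel-size 5 --out records.csv
tubulemorph run config.json --out results/
```

where `config.json` names a localization table or a simulation block per
condition plus any stage parameters (see `tubulemorph run --help`).

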