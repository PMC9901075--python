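# Methods

This note documents the models, conventions and numerical choices behind
`octapvd`, in the spirit of the methods documentation of packages such as
msprime or statsmodels: what is computed, under which assumptions, and
which design decisions were genuinely open.

## Coordinate system and units

Images are 0-based `(row, col)` rasters; row 0 is the top edge and is
treated as superior. All physical quantities are micrometres; the µm/px
scale is derived per axis from the scan extent (default 6×6 mm), so
anisotropic pixels are supported throughout (every distance transform
carries per-axis sampling). For a right eye (OD) in standard en-face
orientation the nasal side is taken as the image-right edge; for a left
eye (OS) it is mirrored. Only the nasal/temporal label assignment depends
on laterality.

## Ring ROI

The measurement region is the 750 µm-wide band immediately outside the
manually delineated disc boundary. The outer boundary is **not** a scaled
concentric ellipse — scaling an ellipse gives a band whose width varies
along the boundary. Instead the ring is the set of pixels whose Euclidean
distance to the rasterized disc region lies in `(0, 750]` µm (a
constant-width Minkowski offset computed with a distance transform), which
is the only construction consistent with a stated *width*. The offset is
computed on a padded canvas so that, when the ring would exceed the image,
the clipped fraction is known exactly; densities are then computed over
the surviving pixels and the clipping is reported as a warning.

Quadrants are the four 90° wedges bounded by the ±45° diagonals through
the ellipse centre — the standard peripapillary S/I/N/T scheme. Angles are
measured in physical space from the image-right axis with superior up;
intervals are half-open (`superior = [45°, 135°)`, `inferior =
[225°, 315°)`), so pixels exactly on a boundary ray have a deterministic
label and the four label sets partition the ring exactly.

The disc ellipse itself is fitted to user-supplied boundary points (or to
the boundary of a user-supplied mask) by least squares in physical µm
coordinates; at least 5 non-collinear points are required, and a mask must
be a single connected component.

## Large-vessel exclusion

No standard algorithm exists for this step, so the package uses a
deliberately parameter-sparse chain that can be validated against
analytic vessel widths: global Otsu threshold → skeletonization → caliber
at each skeleton pixel as twice the Euclidean distance to background →
binary pixels whose nearest skeleton pixel has caliber ≥ `min_caliber_um`
→ dilation by `dilation_um`.

* `min_caliber_um = 30` µm: large peripapillary arterioles/venules are
  several-fold wider than capillaries (capillary lumina are of order
  5–10 µm; en-face capillary traces render at roughly 10–20 µm). The cutoff
  sits in the gap between the two populations.
* `dilation_um = 10` µm guards against the bright partial-volume fringe
  around large vessels leaking into the capillary count.

Both are exposed as configuration. On synthetic scenes with ground-truth
masks, recall of true large-vessel pixels exceeds 0.9 and fewer than 10%
of capillary pixels are falsely captured at these defaults. Large-vessel
segmentation is run per slab; a constant image yields an empty mask with a
warning.

The measured area is the exact set difference
`ring ∖ (vessels ∪ artifacts ∪ disc)`, with per-cause excluded-pixel
counts; an artifact mask covering more than half the ring triggers a
quality warning, and an empty result is an error.

## Perfusion thresholding

Two policies of one operation, reflecting the two readings used in
practice:

* `MEAN_GLOBAL` (default for pVD): threshold `T = a · mean(I | measured)`;
  pixel perfused iff `I ≥ T`.
* `KERNEL_LOCAL` (used for NPA): the image is first replaced by its
  17×17 (289-pixel) sliding-kernel mean (symmetric/reflect padding at the
  borders, computed by windowed pairwise summation so it equals the naive
  neighbourhood mean to machine precision); the same relative rule is then
  applied to the kernel map.

`a` is the dimensionless `adjustment_factor` (allowed range 0.5–2.0,
default 1.0) modelling the manual threshold adjustment graders apply on
low-signal scans; its value is logged in every output record. Ties count
as perfused — an explicit convention that makes the constant-image case
well defined (the comparison carries a 1e-12 relative slack so a tie
cannot be lost to round-off in the mean). A measured area whose mean
intensity is zero has no meaningful relative threshold and raises a
degenerate-threshold error at the operation level; the end-to-end
`quantify` pipeline maps that case (a scan with no flow signal anywhere in
the measured area) to zero density rather than an exception, since a blank
angiogram has no perfusion.

Because all thresholds are relative, per-image min-max normalization on
load is the intensity contract, and multiplying all intensities by any
positive constant leaves the binarization unchanged.

NPA components are 8-connected sets of non-perfused measured pixels; the
minimum component area defaults to 0 (no filter), in which case
`npa_fraction = 1 − perfused fraction` exactly. Quadrant densities are
perfused-over-measured pixel ratios; the mean pVD is area-weighted (total
perfused over total measured), not the unweighted mean of the four
quadrants; an empty quadrant yields NaN, never a division error. pVD is
reported as a fraction in [0, 1]; percentage formatting belongs to the
report layer.

Scans with device signal strength below 7/10 are flagged on load and
refused by `quantify` unless forced.

## Synthetic angiograms

The generator emulates the image model the pipeline assumes: a dark disc
ellipse (default semi-axes 950×800 µm, centred), 8 large vessels traced as
random-walk curves from the disc rim with widths drawn from 40–120 µm, a
fine capillary texture of ~12 µm-wide random curves, multiplicative gamma
speckle (shape k = 25, i.e. speckle contrast ≈ 0.2, plausible for averaged
en-face OCTA), a global intensity scale of `signal_strength/10`, and
optional zeroed shadow patches. The default raster is 1024×1024 over
6×6 mm (≈ 5.9 µm/px).

Per-quadrant capillary coverage inside the ring (default S/T/I/N = 0.52 /
0.48 / 0.55 / 0.50, typical of peripapillary capillary densities) is tuned
by stamping curves until close to target, then adjusted pixel-exactly:
removals only thin structures, and top-up pixels are kept 8-isolated, so
no capillary structure can exceed a 25 µm caliber — safely below the
30 µm large-vessel cutoff. Targets above 0.95 are rejected as unreachable
for a thin-curve texture. Ground-truth fractions are **counted** on the
final masks (ring ∖ vessels ∖ artifacts), never assumed; the same seed
reproduces the scene bit-identically.

Two deliberate idealizations: background (no-flow) pixels are exactly
zero and the speckle is purely multiplicative, so a scene without
vasculature stays blank; and capillaries are only rendered inside the ring
(the only region that is measured). Real scans carry additive system
noise, projection artifacts and capillary texture everywhere, so passing
recovery tests here demonstrate correctness of the measurement chain, not
robustness to every device artifact.

## Synthetic cohorts

`generate_cohort` draws, for eye *i*, sector *s*, visit *t*, slab *l*:

```
pvd = mu[s,l] + delta[s,t,l] + gamma·1[DR, t>baseline, l=DCP] + b_i + e
b_i ~ N(0, sigma_b²),  e ~ N(0, sigma_e²),  clipped to [0, 1]
```

the minimal (compound-symmetric) structure a repeated-measures ANOVA
assumes. Defaults: 33 eyes of which 13 DR; visits baseline / 6 / 12
months; baseline means 0.51–0.58 by sector and slab; decline offsets that
reproduce the qualitative post-operative pattern (superficial plexus:
inferior falls from 6 months, superior/temporal by 12 months; deep plexus:
temporal and inferior from 6 months, superior by 12 months; nasal stable;
magnitudes 0.03–0.04); a DR deficit of −0.06 in the deep plexus after
surgery; `sigma_b = 0.05`, `sigma_e = 0.02`. All effect sizes are
configuration, not constants, so tests never hard-code clinical values as
truths.

## Statistics

* **RM-ANOVA**: one-way within-subjects ANOVA from sums of squares
  (`F = MS_time/MS_error`, df `(T−1, (n−1)(T−1))`), sphericity assumed by
  default with an optional Greenhouse–Geisser epsilon correction (the
  epsilon from the double-centred covariance, clamped to
  `[1/(T−1), 1]`). Incomplete rows are dropped listwise with a reported
  count. Identical columns give `F = 0, p = 1`; a nonzero time effect with
  zero error variance is reported as `p = 0` with a degenerate flag rather
  than an exception. Post-hoc: pairwise paired t tests, Bonferroni
  multiplied by the number of pairs.
* **Mann–Whitney U** (equivalently the Wilcoxon rank-sum test): midranks
  for ties; exact permutation enumeration for `n_a + n_b ≤ 12`, otherwise
  a tie-corrected normal approximation with continuity correction.
* **Wilcoxon signed-rank**: zeros dropped, midranks on magnitudes,
  `W = min(W+, W−)`; exact sign-pattern enumeration for `n ≤ 15`,
  otherwise the tie-corrected normal approximation. All-zero differences
  raise an explicit error.
* **Fisher's exact** on 2×2 tables: two-sided p as the sum of
  hypergeometric probabilities not exceeding the observed table's (with a
  1e-9 relative slack against floating-point ties); a zero margin gives
  p = 1.
* Two-sided p-values throughout are defined by the enumeration convention
  `P(|T − E[T]| ≥ |t_obs − E[T]|)`; all tests use α = 0.05 by default.
* **Group-difference table**: per slab × visit × sector (plus the per-eye
  mean), `mean(no-DR) − mean(DR)` with a Mann–Whitney p per cell. No
  multiplicity correction is applied across cells by default (matching how
  such tables are conventionally starred); a Bonferroni-across-cells
  option exists.

## Problem sizes and calibration checks

The test suite and the acceptance script validate, at sizes chosen to keep
a full run around a minute each: kernel-map exactness against a naive
double-loop oracle on images up to 64×64; ring area against the analytic
annulus on the full 1024² raster; density recovery on three noise-free
scenes (≤ 0.02 per quadrant) and 20 speckled scenes (≤ 0.05); pVD/NPA
complementarity on 100 random maps (machine precision); rank/exact tests
against brute-force enumeration on all instances with n ≤ 8; and the
repeated-measures comparison's empirical type-I error (0.05 ± 0.02 over
1000 null cohorts) and power (≥ 0.8 over 500 cohorts at the default
inferior-decline effect, n = 33).

## Known limitations

* The disc boundary is an input (the delineation is manual by design);
  no automatic disc detection is attempted.
* The large-vessel rule is intensity/caliber-based; it does not classify
  arterioles vs venules and can absorb capillary pixels fused to a vessel
  within the dilation margin.
* The synthetic texture is a stochastic curve model, not a hemodynamic or
  speckle-physics simulation; absolute density values on real scans depend
  on device rendering and are only comparable within a protocol.
* Reported provenance (config hash, tool version) is embedded in CSV
  outputs; timestamps are deliberately kept out of data files so identical
  runs produce byte-identical reports.
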