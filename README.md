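# octapvd

Peripapillary vessel-density (pVD) quantification for en-face OCT
angiography, with a fully synthetic test bed.

## The problem

After vitreoretinal surgery (e.g. pars plana vitrectomy with internal
limiting membrane peeling for an epiretinal membrane), the capillary
network around the optic nerve head can thin progressively. OCT
angiography (OCTA) renders retinal blood flow as bright pixels in en-face
slab images, so capillary loss is measurable — but only after a careful
chain of image processing: the optic disc and the large retinal vessels
must not count as capillaries, the measurement region must be anatomically
standardized, and the perfused/non-perfused decision must be robust to the
scan's overall signal level.

`octapvd` implements that chain for disc-centred 6×6 mm² en-face slabs
(superficial and deep capillary plexus), for researchers who need
reproducible quadrant densities and longitudinal statistics:

1. **Geometry** — the disc boundary (supplied manually as an ellipse,
   boundary points or a mask) is fitted with a least-squares ellipse; the
   region of interest is the **750 µm-wide elliptical ring** immediately
   outside the disc, built as a constant-width Euclidean-distance offset
   and split into superior / inferior / nasal / temporal quadrants by the
   ±45° diagonals (nasal/temporal assignment follows eye laterality).
2. **Large-vessel exclusion** — Otsu threshold → skeleton → distance-
   transform caliber; bright structures with caliber ≥ 30 µm are excluded
   (plus a 10 µm dilation), together with the disc and optional manual
   artifact masks.
3. **Perfusion binarization** — a pixel is perfused iff its intensity is at
   least `adjustment_factor ×` the mean intensity over the measured area
   (`MEAN_GLOBAL`, used for pVD), or iff its **17×17 (289 px)**
   sliding-kernel mean passes the same relative rule (`KERNEL_LOCAL`, used
   for non-perfusion-area detection). Per quadrant *s*,

   `pVD_s = (perfused pixels in s) / (measured pixels in s)`,

   and the mean pVD is the area-weighted ratio over all quadrants. The
   non-perfusion area (NPA) is the set of 8-connected non-perfused
   components, reported as a fraction of the measured area. Scans with
   device signal strength below 7/10 are refused (overridable).
4. **Synthetic data** — seeded generators render angiograms with exact
   ground-truth masks and per-quadrant perfusion fractions, and draw
   longitudinal cohorts (33 eyes × 3 visits × 2 slabs × 4 quadrants, 13
   diabetic-retinopathy eyes) from an additive random-intercept model.
5. **Statistics** — one-way repeated-measures ANOVA across visits with
   Bonferroni post-hoc, Mann–Whitney U, Wilcoxon signed-rank and Fisher's
   exact tests (exact enumeration at small n), and the per-cell
   `mean(no-DR) − mean(DR)` group-difference table.

## Worked example

```python
from octapvd import SceneConfig, Sector, generate_angiogram, quantify

config = SceneConfig(seed=1)                  # 1024x1024, 6x6 mm, speckle on
angiogram, truth = generate_angiogram(config)
result = quantify(angiogram, truth.disc)      # full pipeline, defaults

record = result.record
for s in Sector:
    print(f"{s.value:>9}: pVD = {record.sector_value(s):.3f} "
          f"(truth {truth.sector_fractions[s.value]:.3f})")
print(f"     mean: pVD = {record.pvd_mean:.3f}, NPA fraction = "
      f"{result.npa.npa_fraction:.3f}, threshold = {result.threshold_used:.3f}")
```

prints

```
 superior: pVD = 0.521 (truth 0.520)
 inferior: pVD = 0.552 (truth 0.550)
    nasal: pVD = 0.504 (truth 0.500)
 temporal: pVD = 0.489 (truth 0.480)
     mean: pVD = 0.517, NPA fraction = 0.444, threshold = 0.373
```

Each quadrant density is the perfused fraction of the ring after disc,
large-vessel and artifact exclusion; the generator's exact pixel-count
ground truth is recovered to well within ±0.05 despite multiplicative
speckle. The NPA fraction comes from the kernel-local binarization and so
is not exactly `1 − mean pVD` (the two policies agree only when the same
map is used for both).

The same pipeline is scriptable from the shell:

```sh
octapvd simulate --seed 1 --out scene/
octapvd quantify --image scene/angiogram.png --disc scene/disc.json \
        --slab SCP --out report.csv
octapvd simulate --cohort --seed 1 --out cohort/
octapvd cohort-stats --in cohort/cohort.csv --out stats.csv
```

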