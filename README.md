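# geoparticle

Characterization toolkit for respirable geogenic particles — desert dust,
volcanic ash and similar mineral PM₁₀ — aimed at exposure-science and
inhalation-toxicology workflows. It covers the desk-side computations of a
typical physicochemical characterization campaign:

- **SEM-EDS phase mapping** (`geoparticle.phasemap`): combine per-element
  X-ray intensity maps into a labeled mineral-phase map. For each phase the
  selected element maps are flattened by a per-pixel **median**, thresholded
  (inclusive ≥) and despeckled with a binary median filter; the composite is
  assembled by painting phases in **descending mask-area order**, so where
  masks overlap the smallest claimant phase wins and large phases cannot mask
  small ones. Output: label raster, legend, and an area-fraction table in
  which phase % + unassigned % = 100. An inter-analyst comparison utility
  reports |Δ area %| per phase.
- **Particle morphometry** (`geoparticle.morphometry`): grayscale + size
  threshold segmentation (8-connected), then per-particle
  ECD = 2√(A_p/π), minimum/maximum Feret diameters by rotating calipers on
  the convex hull of pixel corners, aspect ratio D_min/D_max, solidity
  A_p/A_CH, and border-traced perimeter; Tukey box-plot summaries
  (median, hinges, 1.5×IQR whiskers, outliers).
- **Size-distribution metrics** (`geoparticle.psd`): D50 and fractions finer
  than 10/4/2.5/1 μm from binned distributions, with log-linear
  interpolation, on volume and (sphere-assumption) number bases.
- **Bulk geochemistry** (`geoparticle.geochem`): oxide totals with loss on
  ignition, total alkali Na₂O + K₂O, and total-alkali–silica (TAS)
  classification against the standard Le Bas field polygons.
- **Assay arithmetic** (`geoparticle.assay`): oxidative potential as the
  blank-corrected, mass-normalized depletion rate of DTT or ascorbic acid
  (OLS slope; LOD = 3 × SD of blanks), plus air–liquid-interface deposition
  dose (μg/cm²), seeding density and protein-normalized cytokine fold change.
- **Synthetic fixtures** (`geoparticle.fixtures`): multi-phase EDS scenes,
  parametric particle silhouettes, lognormal size distributions and linear
  depletion series — all with analytic ground truth and seeded randomness.

## Worked example

Phase-map a noisy three-phase synthetic scene and recover area fractions
(`python examples/phase_mapping.py`):

```
phase        recovered %   truth %
quartz            24.51     25.00
calcite            8.81      8.81
feldspar           8.46      8.51
unassigned        58.21
```

At noise equal to 10% of the signal–background gap and radius-1
despeckling, recovered fractions land within ~1% absolute of ground truth,
and the rows plus `unassigned` always total 100% of the frame.

Size metrics on both bases (`python examples/size_distribution.py`):

```
volume basis: D50 = 3.90 um   <10 um: 95%, <4 um: 52%, <2.5 um: 22%, <1 um: 1%
number basis: D50 = 1.39 um   <10 um: 100%, <4 um: 96%, <2.5 um: 84%, <1 um: 28%
```

The volume-median diameter (3.9 μm) reflects where the mass sits; converting
to a number basis (weights ∝ v/d̄³) shows most particles by count are far
finer — the pattern that matters when counting deposited particles rather
than weighing them.

The other examples (`particle_shapes.py`, `geochemistry.py`,
`oxidative_potential.py`) demonstrate shape metrics against analytic truth,
TAS classification (a 53.9 wt.% SiO₂ / 4.1 wt.% alkali ash is a basaltic
andesite), and the OP pipeline.

A thin CLI mirrors the library: `geoparticle phasemap|morph|psd|geochem|op|dose|fixtures --help`.

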