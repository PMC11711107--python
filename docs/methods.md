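# Methods

This note documents the models, conventions and numerical choices behind
`geoparticle`, and what the synthetic fixtures do and do not emulate.

## Phase mapping from SEM-EDS element maps

**Model.** A mineral phase is operationally defined as the set of pixels
whose flattened element intensity exceeds a threshold. For a phase defined
on elements E, the flattened image is the per-pixel **median** across the
selected element maps — robust to one anomalous map when |E| ≥ 3, and the
identity for |E| = 1. Thresholding is **inclusive** (mask = flat ≥ t), so
boundary-valued pixels are kept; this must be fixed one way or the other
for bit-exact reproducibility. Despeckling is a binary median filter over a
(2r+1)×(2r+1) square window with edge-repeating reflect padding; r = 1 by
default (removes isolated speckle pixels, the standard despeckle), r = 0
disables it and is exactly the identity.

**Composite assembly.** Masks are painted onto the composite in strictly
descending mask-area order, ties broken by ascending phase name. Later
(smaller) phases overwrite earlier (larger) ones, so a pixel claimed by
several phases ends with its smallest-area claimant — small phases are
never masked by large ones. For equal-area claimants the later-painted
(lexicographically larger) name wins; the property-test oracle encodes the
same rule. The result is independent of the order in which phase
definitions are supplied.

**Quantification.** Area fractions are measured on the final labels.
Unassigned pixels are an explicit class, so phase % + unassigned % = 100
(±0.01 enforced as an invariant). Because it is ambiguous whether fractions
should be normalized to frame area or to assigned (particle) area, the
proportion table reports both: `rows` (frame-based) and
`rows_of_quantified` (renormalized over assigned pixels).

**Recipes.** Thresholds, element sets, denoise radii and RGB colors come
from a declarative YAML recipe rather than interactive selection, making a
mapping fully reproducible. Named element-set presets (e.g. *plagioclase
feldspar* → {Al, Si, Ca, Na}) ship as editable package data; they are
starting points, not fixed chemistry.

**Limitations.** No spectral deconvolution: two phases sharing an element
at similar intensity cannot be separated by thresholding alone (the
discriminating thresholds in the examples are chosen strictly between the
competing intensity levels). Inter-analyst disagreement is quantified, not
resolved.

## Particle morphometry

**Segmentation.** Global grayscale threshold (either polarity), 8-connected
component labeling, minimum-area filter. Frame-touching components are
flagged and excluded from summaries by default — a truncated particle
biases Feret and solidity — with a toggle to keep them.

**Conventions.**

- Feret diameters are computed on the convex hull of the particle's pixel
  *corner* points, so a 1-pixel particle has extent 1 px rather than 0.
  D_max is the hull's point-set diameter; D_min is the rotating-calipers
  width (minimum over hull edges of the farthest-vertex distance).
- ECD = 2√(A_p/π) with A_p = pixel count × pixel_size².
- Solidity = A_p / A_CH with A_CH the shoelace area of the corner hull.
  Digitization bias: for *rotated* convex shapes the corner hull exceeds
  the true outline by roughly half the perimeter in pixel units, so
  measured solidity of a convex particle approaches 1 from below as
  ~1 − 0.5·P/A; agreement with analytic values to 2% needs the minor
  dimension ≳ 100 px. Axis-aligned shapes are exact (square → 1,
  plus-sign → 5/7).
- A 1-pixel region takes aspect ratio 1 and solidity 1 by convention.
- Perimeter is Moore border tracing over boundary pixel centers with unit
  orthogonal and √2 diagonal steps. It is reported for completeness but
  feeds neither aspect ratio nor solidity; like all center-chain tracers it
  underestimates small-particle outlines.

**Summaries.** Tukey convention: median and hinges by linear interpolation
of order statistics (type-7 quartiles — pinned so tests are exact),
whiskers at the most extreme points within 1.5×IQR of the hinges, points
beyond reported individually. The default particle filter keeps
ECD > 0.5 μm (strict inequality).

## Size-distribution metrics

Distributions arrive as bin edges plus fractions (the optical inversion
inside a laser-diffraction instrument is out of scope; the module consumes
exported tables). Representative bin diameter is the geometric mean of its
edges and all interpolation is linear in log₁₀(diameter) — the natural
choice for wide log-spaced sizing grids. D50 solves cumulative = 0.5;
sub-cutoff fractions interpolate the cumulative curve the same way, so
frac_below(D50) = 50% by construction. Volume→number conversion assumes
spheres (number weight ∝ v/d̄³, renormalized), the only shape-free option;
it is exactly inverted by the reverse conversion. For any distribution
with ≥ 2 occupied bins the number-basis D50 lies below the volume-basis
D50, since d³-weighting shifts mass to coarse bins.

## Bulk geochemistry

Totals are Σ oxides + LOI₁₁₀ + LOI₁₀₀₀, rounded to one decimal (the
precision oxide tables are reported at). Note that a total computed from
rounded components can differ from a total computed on unrounded data by
±0.2 — totals are bookkeeping, not a closure test. TAS classification
locates (SiO₂, Na₂O+K₂O) in the standard Le Bas field polygons, shipped as
editable YAML. Boundary points go to the field whose centroid has lower
alkali, then lower silica — a fixed, documented tie rule chosen for
determinism. The very-high-alkali branch (tephrite through foidite) is not
encoded and returns "unclassified"; the diagram is meaningful for magmatic
compositions (volcanic ash), nominal for sedimentary dust.

## Oxidative potential and exposure arithmetic

The depletion rate is −slope of ordinary least squares of remaining
reagent (nmol) vs time (min). The "linear section" is not algorithmically
standardized, so the default fits all points and an optional `auto` window
picks the contiguous run of ≥ 3 points maximizing R² (ties prefer the
longer, then earlier, window); the window used is always reported.
Blank correction subtracts the mean of ≥ 3 laboratory blank rates;
LOD = 3 × sample SD (n−1 denominator — appropriate for n = 3 blanks) of
those rates. Sub-LOD results are flagged, never censored to zero or
dropped. Mass normalization divides by user-supplied well mass (μg),
typically 2 μg per well; absorbance→nmol calibration is accepted as input
rather than modeled. Deposition dose for pseudo-ALI exposure is
concentration × applied volume / insert growth area (μg/cm²); cytokine
fold change divides protein-normalized concentrations and raises on an
unquantifiable (zero) untreated baseline rather than returning infinity.

## Synthetic fixtures

Scenes paint per-element mean intensities over geometric regions on a
uniform background and add seeded Gaussian noise (clipped at zero to keep
intensities valid); overlapping regions are rejected so the truth labeling
is unambiguous. Silhouettes are rasterized by 4× supersampled area
coverage thresholded at 50%, giving stable analytic-vs-measured
comparisons. Lognormal PSDs are CDF differences on a log grid spanning
±4 log-σ (truncation beyond 1% warns). Depletion series are a₀ − rate·t
plus seeded noise. All generators are pure functions of (spec, seed).

What the fixtures do **not** emulate: X-ray physics (spectral overlap,
detector noise correlations between element maps), touching/agglomerated
particles, instrument smoothing of size distributions, or assay chemistry
(DTNB kinetics, calibration drift). Passing tests therefore demonstrate
the *computational* contracts — flattening, assembly, measurement and the
arithmetic chains — on data with known truth, not robustness to every
artifact of real acquisitions.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems chosen to exercise every code path with analytic or brute-force
cross-checks: 96×96 three-phase scenes, 50 random ≤ 32×32 scenes against
the per-pixel oracle, silhouettes up to ~1000 px across, 64-bin
distributions, 31-point depletion series. These sizes keep the
brute-force oracles (per-pixel loops, 0.1°-step caliper scans) exact and
fast while leaving the implementations the only scalable path.
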