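# Methods

This note documents the models, conventions and design choices behind
`cytoquant`, and what the synthetic validation does and does not show
about real microscope data.

## Pipeline definition

**Projection.** Stacks are reduced by summation along z, per channel, with
float64 accumulation; integer-valued voxels therefore project to exact
integer sums.  Sum (rather than maximum) projection preserves total
fluorophore content per column, which is what makes `S` and `MFI`
meaningful as content measures.

**8-bit rescale.** `out = round(255·(v − min)/(max − min))` with half-up
rounding, fixed for cross-platform byte reproducibility.  A constant
projection maps to all zeros rather than an arbitrary constant: this
keeps the downstream "non-zero pixel" count `N` at zero for structureless
images instead of inventing signal.  Rescaling is per cell, so absolute
intensities are not comparable across cells — by design, as in the
flow-cytometry analogy — while ratios and dispersions within a cell are.

**Otsu threshold.** The threshold maximises the between-class variance of
the 256-bin histogram over classes `{v ≤ t}` / `{v > t}`; foreground is
`v > t`.  Between-class variances are compared in exact integer
arithmetic (cross-multiplied rationals), so the documented tie-break —
the smallest maximising threshold — is bit-exact on every platform.  A
single-valued input is flagged `single_class` and returns that value, so
the foreground is empty rather than arbitrary.  The library
implementation (`skimage.filters.threshold_otsu`) is used as an
independent cross-check in the test suite, never as the implementation,
because its tie and binning conventions are not pinned to this contract.

**Cell mask.** The cell-level Otsu is computed on the marker-channel
projection by default (the channel being quantified), configurable to the
DAPI channel or the union of both foregrounds.  The largest connected
component under 8-connectivity (configurable to 4) is kept; size ties
resolve to the component whose first pixel comes earliest in raster
order.  An empty foreground warns and propagates as a QC flag instead of
raising.

**Nucleus mask.** Otsu restricted to the DAPI pixels inside the cell
mask; all resulting components are retained, because granulocyte nuclei
are lobed and genuinely non-contiguous at our resolution.  No
largest-component step is applied to the nucleus.  Constant in-cell DAPI
flags the cell and treats it as all-cytoplasm.

**Compartments.** `nucleus := cell ∧ nucleus`, `cytoplasm := cell ∧
¬nucleus` — the only mask algebra consistent with an exact
nuclear/cytoplasmic partition of the cell.  The partition identity
`|nucleus| + |cytoplasm| = |cell|` holds exactly and is asserted by
construction.

**Histogram metrics.** `H(k)` counts masked pixels with value exactly
`k`, `k ∈ [1, 255]`; zero-valued pixels are excluded by the domain, so
adding or removing them changes nothing (tested property).  `N = Σ H(k)`,
`S = Σ k·H(k)`, `MFI = S/N`; an empty compartment yields NaN, never 0.
Compartments with `N` below a configurable minimum (default 10) are
flagged low-quality rather than suppressed.

**HWHM.** The mode bin `k*` is the smallest maximiser; the half-max level
is `H(k*)/2`.  Scanning outward, the first bin strictly below the level
defines a crossing, interpolated linearly between that bin and its inner
neighbour; a plateau exactly at the level therefore resolves to its
outermost edge.  HWHM is half the full width between the two crossings
(a one-sided mode-to-crossing variant is available via
`hwhm_mode="one_sided"`).  Two conventions are fixed deliberately:

* a histogram with all mass in one bin has **HWHM = 0** — a point
  distribution has zero dispersion.  Pure interpolation through the two
  neighbouring empty bins would instead give 0.5 bin widths, which would
  report spread where there is none;
* a side that never drops below half-max inside [1, 255] clamps to the
  domain edge and sets a `truncated` flag, so saturated histograms are
  visible in QC rather than silently narrow.

Under these rules the analytic checks are sharp: a sampled Gaussian with
σ = 10 gives HWHM ≈ σ√(2 ln 2) ≈ 11.77 (within binning error), and the
triangular histogram peaking at 100 with base 80–120 gives exactly 10.

**Statistics.** The two-group (junior/senior) contrast uses the two-sided
Mann–Whitney U test — exact enumeration for tie-free samples with both
n ≤ 20, otherwise the normal approximation with tie and continuity
correction.  Multi-condition HWHM contrasts use one-way ANOVA with Tukey
HSD post-hoc (`statsmodels`).  Cells are treated as independent
observations by default, matching the per-cell n of the cohort design;
because cell-level pseudo-replication is a known hazard when donors
differ, a donor-aggregated variant (per-donor medians) is available via
`donor_aggregate=True`.  No multiple-testing correction is applied across
report strata by default; a Holm option exists.  Missing responses are
dropped with a logged count; an all-missing group is an error naming the
group.

## The phantom generator

The generator emulates single sorted myeloid cells mounted on adhesion
slides and imaged at dx = dy = 0.07 µm, dz = 0.19 µm with 31 optical
sections over a 256 × 256 field (defaults).

**Slab z-profile (default).** Sorted cells settle and flatten on
polysine slides, and the imaged slab (31 × 0.19 ≈ 5.7 µm) lies inside the
cell body; within its footprint the cell therefore spans every section.
The noiseless z-sum projection is then exactly three-level (background /
cytoplasm / nucleus), which is the regime where a single global Otsu
threshold recovers the cell footprint *exactly* — the basis of the
Jaccard = 1.0 recovery checks.  A true ellipsoidal z-profile
(`z_profile="ellipsoid"`) is available; its rim columns thin below one
section, the projection ramps continuously to background, and no global
threshold can reproduce the footprint exactly (measured Jaccard ≈ 0.3–0.9
depending on contrast).  This is a genuine limitation of global
thresholding on sum projections, not of the phantom.

**Nucleus shapes.** 2D cross-sections extruded through the slab: a scaled
ellipse (round), an ellipse minus an offset elliptical bite (kidney,
monocyte-like), or a ring of k ∈ [2, 5] discs (multilobed,
granulocyte-like; the discs may be disjoint, since the chromatin bridges
of a real granulocyte are below this resolution — which also exercises
the non-contiguous-nucleus path of the segmenter).  `nucleus_scale` is
the nucleus:cell volume fraction — exact for round, approximate (a few
percent) for the other shapes.  The nucleus centre is jittered uniformly
within an interior margin of `0.92·r_cell − extent − 3·psf_sigma`, so
optical blur cannot push nuclear signal outside the cell and truth masks
stay valid after convolution.

**Intensities and noise.** Channel means: marker = `mu_nuc` in the
nucleus, `mu_cyt` in the cytoplasm, `background` outside; DAPI =
`mu_dapi` in the nucleus, `background` elsewhere.  Defaults
(120 / 60 / 150 / 5 arbitrary units) were chosen once from a
between-class-variance analysis: with ~35% of the field occupied by the
cell, a nuclear:cytoplasmic marker ratio much above ~2.5 makes the
nucleus–cytoplasm contrast exceed the cell–background contrast, and the
global Otsu threshold jumps inside the cell (it segments the nucleus).
The default ratio of 2 keeps the method in its working regime; the
4× -contrast validation of the quantification stage therefore runs
through ground-truth masks (`quantify_cell(compartment_set=...)`), which
isolates quantification from segmentation failure.  Noise is Gaussian
(default σ = 6 = 0.1·mu_cyt) or scaled Poisson, applied per voxel and
clipped at zero *before* an isotropic Gaussian blur of `psf_sigma`
(default 0.1 µm).  Applying noise before optics is physically debatable
for a rendered phantom; it is chosen for simplicity and fixed.  Detector
saturation is not simulated (acquisition gain is assumed set to fill the
dynamic range without clipping).  Intensities are float32 ≥ 0.

**Cohorts.** A `CohortDesign` is the factorial groups × donors × cell
types × markers × cells-per-donor; the default replication shape is
2 groups × 8 donors × 1 type × 1 marker × 30 cells = 480 records, and
per-cell seeds derive deterministically from the master seed so the whole
cohort is bit-reproducible.  Group- and marker-specific intensity models
allow planting effects; `with_translocation(group, marker, f)` multiplies
that stratum's `mu_cyt` by `f` (the cytoplasmic-shift signature of
nucleus-to-cytoplasm translocation).  No donor-level random effect is
simulated by default: cells are i.i.d. within a group, which is exactly
the regime in which the cell-level tests are calibrated.

## What the synthetic validation shows — and what it does not

Passing tests establish that the *pipeline arithmetic* is exact (Otsu,
partitions, histograms), that segmentation recovers known truth in its
working regime, that the statistics are calibrated (type-I error at the
nominal α under a true null) and powered (a 2× cytoplasmic shift is
detected with power ≈ 1 at the cohort's n, while untouched strata reject
at ≈ α).  They do **not** establish performance on real confocal data:
real images have structured background, uneven illumination, touching
cells, chromatin texture inside nuclei, depth-dependent attenuation and
non-Gaussian PSFs, none of which the phantom models.  In particular, the
rescale step couples compartments — any change in one compartment's
intensity shifts the other's 8-bit values through the shared maximum —
so "unplanted compartment" is not a valid negative control within the
same marker; negative controls must be separate markers or cell types.

## Problem sizes

The validation suite chooses sizes as follows: exactness checks run on
random 16×16–24×24 images (1000 and 500 draws); segmentation recovery on
the full default geometry (256 × 256 × 31, 6 µm cells; 5 noiseless + 50
noisy cells); calibration on 2000 random half-splits of one 480-cell null
pool and power on 6 replicate planted cohorts of 960 cells, both rendered
at a reduced 96 × 96 × 9 field with 2.2 µm cells (the tests are
scale-free in the cell's pixel radius, and boundary effects scale as
perimeter/area — hence the reduced-geometry Jaccard bound of 0.90 in the
unit tests vs 0.95 at full scale).  The default replication run itself
uses the full geometry.

## Known limitations

* One cell of interest per stack; no multi-cell fields, no 3D
  segmentation, no deconvolution, no γH2AX focus counting.
* Global Otsu fails for marker distributions with nuclear:cytoplasmic
  contrast ≳ 2.5 at the default footprint fraction (documented above);
  for such markers the DAPI-seeded or union cell-mask options, or
  external masks, are the supported paths.
* The HWHM of an 8-bit histogram is bounded by the domain; strongly
  saturated cells carry a `truncated` flag and should be filtered on it.
* Equality of nuclear and cytoplasmic MFI at `mu_nuc = mu_cyt` holds in
  the blur-free limit; optical blur darkens the cytoplasm's outer
  boundary against the background, biasing cytoplasmic MFI slightly low.
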