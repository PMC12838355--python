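# cytoquant

Quantification of nuclear versus cytoplasmic fluorescence in single immune
cells from confocal z-stacks — with a synthetic phantom generator and a
cohort-statistics layer that make the whole pipeline testable end to end.

## The problem

Markers of genetic instability such as HMGB1 and γH2AX change their
subcellular localisation when cells senesce: HMGB1 translocates from the
nucleus to the cytoplasm, γH2AX accumulates at nuclear DNA-damage foci.
Flow cytometry summarises whole-cell staining as a mean fluorescence
intensity (MFI) but cannot separate compartments.  `cytoquant` implements
an image-based analog for sorted single cells (granulocytes, monocytes)
imaged as two-channel confocal stacks — one nuclear stain (DAPI), one
antibody marker — and compares the per-compartment readouts between donor
cohorts (e.g. younger vs older age groups).

## The method

For each cell the 3D stack is reduced and quantified as follows:

1. **Z-sum projection** — `P(y,x) = Σ_z I(z,y,x)` per channel, turning the
   volume into a 2D total-fluorophore map.
2. **8-bit rescale** — `P8 = round(255·(P − min)/(max − min))` (half-up),
   normalising out absolute-signal variability between cells.
3. **Otsu threshold** — a global threshold `t` maximising the between-class
   variance of `{v ≤ t}` vs `{v > t}` separates cell from background; the
   largest connected component (8-connectivity) is the cell of interest.
4. **Compartments** — Otsu on the DAPI projection *within* the cell mask
   yields the nucleus (all components kept, so lobed nuclei survive);
   `cytoplasm = cell ∧ ¬nucleus`, an exact partition.
5. **Per-compartment metrics** — from the pixel-value histogram
   `H(k) = #{(y,x) | P8(y,x) = k}`, `k ∈ [1, 255]`:
   * `N` — number of non-zero pixels,
   * `S = Σ_k k·H(k)` — integrated intensity,
   * `MFI = S/N` — mean pixel intensity (the flow-MFI analog),
   * `HWHM` — half-width at half-maximum of `H`, a dispersion measure of
     the fluorophore distribution.
6. **Cohort statistics** — two-sided Mann–Whitney U for the two-group
   contrast per (marker, cell type, compartment) stratum, one-way ANOVA +
   Tukey HSD for multi-condition HWHM contrasts, with the usual star
   conventions (`*` p<0.05 … `****` p<0.0001, `ns`).

Because raw clinical images are rarely shareable, the package ships a
phantom generator: slab-flattened cells with round, kidney (monocyte) or
multilobed (granulocyte) nuclei, configurable nuclear:cytoplasmic marker
ratio, Gaussian or Poisson noise, Gaussian optical blur, and full
ground-truth masks — rendered at confocal pixel geometry
(dx = dy = 0.07 µm, dz = 0.19 µm by default).  See `docs/methods.md` for
the model details and its limitations.

## Worked example

Quantify one synthetic kidney-nucleus monocyte:

```python
import cytoquant as cq

geo = cq.CellGeometry(cell_radii=(2.2, 2.2, 2.2), nucleus_shape="kidney")
acq = cq.AcquisitionGeometry(field_pixels=(96, 96), n_slices=9)
stack, truth = cq.generate_cell_stack(geo, cq.IntensityModel(), acq, seed=7)
rec = cq.quantify_cell(stack)
```

prints (via the obvious f-strings):

```
nuclear:     N=  999  S=  242542  MFI= 242.78  HWHM= 1.22
cytoplasmic: N= 1935  S=  239413  MFI= 123.73  HWHM= 1.23
nuclear/cytoplasmic MFI ratio: 1.96
```

The generator's nuclear:cytoplasmic intensity ratio is 2 (120/60); the
recovered 8-bit MFI ratio of 1.96 reflects it through projection, rescale
and segmentation.  The HWHM ≈ 1.2 intensity units is the histogram spread
produced by the default noise level.

The packaged surrogate experiment — 2 age groups × 8 donors × 30
monocytes, one marker, null scenario — runs from the shell:

```bash
cytoquant replicate --seed 7 --out run/
```

```
480 records quantified; outputs in run/
Nuclear/cytoplasmic staining comparison between groups
(two-sided tests; significance threshold p < 0.05; * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001, ns not significant)

   HMGB1   MO      nuclear   MFI: junior (n=240, median=249.732) vs senior (n=240, median=249.748)  U=28419.5 p=0.8025 [ns]
   HMGB1   MO      nuclear  HWHM: junior (n=240, median=0.879) vs senior (n=240, median=0.916)  U=26519.0 p=0.1334 [ns]
   HMGB1   MO  cytoplasmic   MFI: junior (n=240, median=121.984) vs senior (n=240, median=121.977)  U=29082.0 p=0.853 [ns]
   HMGB1   MO  cytoplasmic  HWHM: junior (n=240, median=0.781) vs senior (n=240, median=0.775)  U=28886.0 p=0.9551 [ns]
```

Both groups are drawn from identical generator parameters, so every
stratum is correctly reported non-significant.  Planting a translocation
effect (`--planted-effect translocation:2.0` doubles the second group's
cytoplasmic marker mean) turns exactly the affected strata significant.

Other subcommands: `simulate` (write a cohort of TIFF stacks + labels
CSV), `quantify` (TIFFs → records CSV), `compare` (records CSV → report),
`make-fixtures` (tiny edge-case corpus).  All accept `--seed`; all outputs
are byte-reproducible for a fixed seed.

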