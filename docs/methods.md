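# Methods

## The index

The Urban Green Carbon Index (UGCI) summarises the carbon condition of an
urban green-space grid cell (30 m × 30 m by default) from four components:

1. **Vegetation C storage** (tC/ha): above- plus belowground vegetation
   carbon stock.
2. **Soil C storage** (tC/ha): soil organic carbon stock.
3. **Net C uptake** (tC/ha/yr): net ecosystem productivity,
   NEP = GPP − R_eco.
4. **Soil C storage potential** (% silt + clay): the fine mineral fraction,
   a proxy for the soil's capacity to stabilise carbon.

Each component is min-max normalised over the analysed grid population,
`X′_ij = (X_ij − X_j,min) / (X_j,max − X_j,min)`, and combined linearly,
`UGCI_i = Σ_j X′_ij W_j`, so UGCI ∈ [0, 1] with low values marking poor
carbon condition.

Weights come from the entropy method standard in multi-criteria decision
analysis: value shares `P_ij = X′_ij / Σ_i X′_ij` give a Shannon entropy
`E_j = −(1/ln n) Σ_i P_ij ln P_ij` (with `0 ln 0 := 0`), and weights are the
renormalised information utilities `W_j = (1 − E_j) / Σ_j (1 − E_j)`. A
component that varies little across space has near-uniform shares, entropy
near 1, and thus a small weight; a spatially constant component is flagged
degenerate, assigned `E_j = 1`, `W_j = 0`, and normalised values 0, so it
cannot perturb the index. Because min-max normalisation is invariant to
positive affine transforms of the raw component, so is the whole index.

Grids are then binned into four management levels — `extremely_low`,
`low`, `moderate`, `high` — at the 25th/50th/75th percentiles of the UGCI
population (linear interpolation between order statistics). A value
exactly on a cut-off joins the upper level, matching the usual
"< Q1 / Q1–Q2 / Q2–Q3 / ≥ Q3" reporting convention.

### Normalisation population

Components are only defined on vegetated cells (impervious and water cells
are nodata in the component rasters), so the normalisation population is
the set of valid vegetated grids. When users supply component rasters with
values on non-vegetated cells, the stack mask — the intersection of
per-component validity — defines the population.

## Prescription by ternary decomposition

For `low` and `extremely_low` grids, the three highest-weight components
(ties broken by canonical component order) are renormalised to simplex
coordinates `X = a/(a+b+c)` etc., where `a, b, c` are the min-max values.
Coordinates are invariant to common rescaling of `(a, b, c)`; a grid with
`a = b = c = 0` has no direction on the simplex and is reported as fully
depleted rather than plotted.

Interpretation follows the geometry of the ternary plot: a point near
vertex *j* means component *j* is relatively strong and the **other two**
are the limited pair; a point near the centre means all three components
are uniformly low. Numeric cut-offs for "near" are not standardised, so
the package exposes three thresholds:

- `vertex_threshold = 0.5`: a point is vertex-dominant when its largest
  proportion reaches 0.5 (the dominant component holds at least half the
  total).
- `center_radius = 0.15`: Euclidean distance from (⅓, ⅓, ⅓) within which a
  point counts as centre. 0.15 covers roughly the central fifth of the
  simplex.
- `limited_threshold = 0.15`: for points that are neither vertex-dominant
  nor central (typically near an edge of the triangle), any component whose
  proportion is ≤ 0.15 is flagged limited. This is what catches the common
  case of one component several-fold weaker than the other two, whose point
  lies near the midpoint of an edge — e.g. proportions (0.48, 0.48, 0.05)
  flag the third component. Without this rule such grids would carry a
  category but no actionable limitation.

All three are configuration keys; the defaults are design choices of this
package, not published constants.

Management strategies are data, not code: `strategies.yaml` maps each
land-cover class to per-component and whole-bundle recommendation texts
(litter retention and shade-tolerant understory for forest soil-C limits,
conservation-agriculture bundles for cropland, aeration plus organic
amendments for parks, multilayer drought-tolerant plantings and
decompaction for roadside strips). Practitioners can localise the wording
without touching code.

## Carbon-component equations

- **Vegetation stock**: `VCS = A · V · BEF · D · (1+R) · CF` (tC) from
  stock-change coefficients (growing stock volume, biomass expansion
  factor, wood density, root:shoot ratio, carbon fraction). Open-grown
  urban street trees assessed with natural-forest coefficients are scaled
  by the correction factor 0.8.
- **Allometric ground truth**: `Σ_j Σ_i a_j · DBH_ij^{b_j}` over an
  inventory of measured trees. The unit of the result is the unit the
  coefficients were fitted in; the stylised coefficients shipped with the
  synthetic generator yield tC per tree from DBH in cm.
- **GPP** (μmol CO₂ m⁻² s⁻¹):
  `LUE · nPAR · fPAR · (0.382·T_air + 0.0905·VPD + 17.72) ·
  (1+LSWI)/(1+LSWI_max)`. The temperature/VPD scalar coefficients are
  fixed empirical constants; the water scalar equals 1 at the
  growing-season LSWI maximum. No floor at zero is applied: the formula is
  evaluated as stated.
- **Ecosystem respiration**: `R_eco = (1 + 0.20·GPP_acc) ·
  exp(1.16 · T_air / max(T_air))`, strictly increasing in accumulated
  productivity and temperature. `GPP_acc` is the trailing 7-day (168 h)
  mean of hourly GPP; shorter leading windows use available history. The
  `max(T_air)` normaliser is the maximum over the evaluated series by
  default and is caller-configurable.
- **Annual NEP**: hourly `GPP − R_eco` integrated over the year and
  converted with 12 g C per mol CO₂ and 10⁴ m² per hectare; a sustained
  net flux of 1 μmol CO₂ m⁻² s⁻¹ over a 365-day year equals
  3.78432 tC ha⁻¹ yr⁻¹ (leap years: actual second count via the series
  length). Negative totals are net carbon emissions.

The fitted machine-learning layers that sit on top of these equations in
operational use (random-forest GPP, roadside bias correction, digital soil
mapping of texture) are out of scope; the corresponding rasters and driver
series are inputs here.

## Grid conventions

Rasters are row-major with 0-based indices, cell identity at the cell
centre, and all distances in metres from `cell_size`. GeoTIFF I/O uses the
standard georeferencing tags (pixel scale, tiepoint, EPSG geokey, GDAL
nodata). Two regridding contracts are provided: dominant-class block
aggregation for categorical rasters (modal class among valid fine cells,
ties to the smallest class code; all-nodata blocks stay nodata) and
bilinear resampling for continuous rasters (interpolation between coarse
cell centres; cells outside the support and nodata holes take the nearest
valid coarse value, which keeps outputs inside the coarse value range).

## Edge analysis

Patches are connected components of equal class (8-connected by default,
configurable to 4). A patch cell is an edge cell when its centre lies
within `distance_m` (default 30 m) of the centre of any cell of another
class or nodata; space beyond the raster border counts as nodata. At 30 m
cells this reduces to the outermost one-cell ring, and the implementation
(per-class Euclidean distance transform) agrees exactly with an all-pairs
centre-distance computation. Edge cells belong to their own patch; the
ring outside belongs to the neighbouring class. Edge cells are classified
by their out-of-class neighbours as impervious-adjacent, green-adjacent,
or mixed (mixed also covers edge cells whose only foreign contact is
nodata or the border).

Edge-vs-interior contrasts use Welch's unequal-variance t-test per
land-cover class, reporting the edge deficit
`100 · (interior − edge) / interior` (percent lower at the edge).
Patch-size association uses Pearson correlation of log patch area against
per-patch mean UGCI (the log base does not affect r); it requires at least
three patches and reports an undefined-r signal when areas or means are
constant.

## Synthetic landscapes

The generator produces the study conditions for every test: a fragmented
mosaic of forest, urban park, agricultural land, roadside vegetation,
water, and an impervious background, grown from random seed points by
jittered-priority region growing until each class meets its area budget
(target fractions 0.30 / 0.15 / 0.20 / 0.05 / 0.05, remainder impervious;
realised fractions are within a few percentage points at 200 × 200).
Component values are truncated Gaussians (lower bound 0; 100 for the
texture percentage) around per-class means, with within-class noise
expressed as a relative standard deviation (default 0.05). An optional
multiplicative edge deficit (scalar or per-component) scales component
values in edge cells after sampling, giving a known ground truth for the
edge-effect analytics.

Default class profiles (vegetation C tC/ha, soil C tC/ha, net uptake
tC/ha/yr, silt+clay %):

| class        | veg C | soil C | NEP | silt+clay |
|--------------|------:|-------:|----:|----------:|
| forest       |    80 |     45 |  10 |        35 |
| park         |    35 |     30 |   5 |        30 |
| agricultural |     8 |     20 |   3 |        40 |
| roadside     |     5 |      8 | 0.5 |         8 |

These are stylised, not calibrated to any city: class contrasts are strong
and monotone (forest ≫ park ≫ roadside for the biomass-linked components),
and the roadside class — young plantings on reconstructed, sand-dominated
engineered fill — anchors every component's minimum near zero. The
anchoring is deliberate: min-max normalisation is affine, not linear, so a
multiplicative edge deficit on raw components carries through to the
normalised index only when component minima are close to zero. With these
profiles a 30 % injected deficit is measured back from the UGCI surface on
the forest class (the class with the largest patches and hence the most
interior cells) at ≈ 32 %, within the ±5-percentage-point tolerance the
recovery experiment uses.

What the generator does **not** emulate: realistic urban morphology (road
networks, building footprints), spatially autocorrelated within-class
variation, cross-component correlation beyond what class membership
induces, seasonality, or measurement error structure of real remote-sensing
products. Passing tests therefore demonstrate the correctness of the
algorithms and the identifiability of injected effects under clean
conditions — not that any particular city will show these effect sizes.

## Problem sizes and numerical choices

The stock analyses run on 200 × 200 mosaics (40 000 cells, 28 000
vegetated), which gives thousands of edge and interior cells per major
class — comfortably enough for stable entropy weights and t-tests — while
keeping the full test suite and the reproduction script in the seconds
range. The edge-deficit recovery experiment uses 20 replicate seeds.

Quartiles use linear interpolation between order statistics. Entropy uses
natural logarithms with `0 ln 0 := 0`. Dominant-class ties break to the
smallest class code; top-component ties keep canonical component order;
the ternary argmax tie goes to the first component. All randomness flows
from a single integer seed per run (`numpy.random.default_rng`), making
every artifact byte-reproducible.

## Known limitations

- The entropy weights depend on the analysed population: cropping the
  study area changes weights and therefore UGCI values. This is inherent
  to the method, not an implementation artifact.
- Quartile levels are relative to the analysed landscape; they are
  management priorities, not absolute carbon ratings.
- The edge-deficit percent difference is measured on the normalised index;
  with component minima far above zero it will overstate a multiplicative
  raw-component deficit (see the anchoring discussion above).
- CRS handling is validation-only (EPSG code round-trip); reprojection is
  out of scope, and inputs must already be co-registered.
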