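# ugci — Urban Green Carbon Index toolkit

`ugci` is a decision-support toolkit for municipal carbon management of
urban green space. It rates every grid cell of a city (30 m × 30 m by
default) on a 0–1 **Urban Green Carbon Index** built from four carbon
components — vegetation C storage (tC/ha), soil C storage (tC/ha), net C
uptake (NEP, tC/ha/yr), and soil C storage potential (% silt + clay) —
then tells planners *which* component to fix in the worst-rated cells and
*how*, with land-cover-specific management strategies. It is aimed at
environmental analysts and urban-forestry planners working with gridded
carbon data.

## The method

**Diagnosis.** Components are min-max normalised over the grid population,
`X′_ij = (X_ij − X_j,min)/(X_j,max − X_j,min)`, and combined linearly:

    UGCI_i = Σ_j X′_ij · W_j,      W_j = (1 − E_j) / Σ_j (1 − E_j),

where `E_j = −(1/ln n) Σ_i P_ij ln P_ij` is the Shannon entropy of the
component's value shares `P_ij = X′_ij / Σ_i X′_ij` (0 ln 0 := 0). A
spatially variable component is informative and gets a large weight; a
near-uniform one gets a small weight; a constant one gets exactly zero.
Cells are then binned into `extremely_low / low / moderate / high`
management levels at the UGCI quartiles.

**Prescription.** For `low` and `extremely_low` cells, the three
top-weight components `(a, b, c)` are projected onto a ternary plot via
`X = a/(a+b+c)` etc. Points near a vertex have two limited components,
points near the centre are uniformly depleted, and points near an edge
midpoint have one strongly limited component; each diagnosis maps to an
editable strategy table (`strategies.yaml`) keyed by land-cover class.

The package also ships the closed-form carbon-component models (IPCC-style
stock equation with the 0.8 open-grown-tree correction, DBH allometry,
light-use-efficiency GPP, productivity–temperature ecosystem respiration,
hourly-to-annual NEP integration), patch/edge landscape analytics with
Welch t-tests and patch-size correlations, and a seeded synthetic
landscape generator so the full pipeline runs without any external data.
The diagnosis core is also exposed as scikit-learn estimators
(`EntropyWeightedIndex`, `QuartileLevelClassifier`) that compose with
sklearn pipelines. See `docs/methods.md` for the full model description
and design choices.

## Worked example

```bash
cat > demo.yaml <<'YAML'
seed: 1
out_dir: demo_out
synthetic:
  shape: [200, 200]
  noise: 0.05
  edge_deficit: 0.7     # 30% multiplicative deficit in patch-edge cells
YAML

ugci simulate --config demo.yaml
ugci diagnose --config demo.yaml
ugci prescribe --config demo.yaml
ugci edges    --config demo.yaml
```

`diagnose` logs

    n=28000 grids | weights [0.4799, 0.1757, 0.2549, 0.0895] | thresholds [0.2131, 0.4161, 0.8117]

i.e. 28 000 vegetated cells were scored; vegetation C is the most
informative component (weight 0.48) and the weakly varying silt+clay
fraction the least (0.09, and therefore excluded from the ternary
decomposition, which uses the top three); the quartile cut-offs split the
index surface into the four management levels. `prescribe` writes
`prescriptions.csv` with one row per low/extremely-low cell — here 14 000
rows, of which 4 035 are centre-category (all three components uniformly
low) — plus per-class ternary figures. `edges` writes
`edge_comparison.csv`:

    landcover,n_edge,n_interior,edge_mean,interior_mean,pct_lower,p
    forest,1420,10580,0.561,0.822,31.8,<0.001
    park,1066,4934,0.274,0.413,33.6,<0.001

The 30 % edge deficit injected by the generator is recovered from the
index surface: forest edges score 31.8 % lower than forest interiors
(Welch t-test, p < 0.001).

The same pipeline runs on real data by replacing the `synthetic:` block
with an `inputs:` block pointing at five co-registered GeoTIFFs
(land cover plus the four components).

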