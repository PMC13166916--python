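"""Synthetic fragmented urban land-cover mosaics and component rasters.

The generator emulates the kind of landscape the index framework targets:
a city mosaic of forest, urban park, agricultural land, roadside
vegetation, impervious surface, and water, produced by seeded region
growing; per-class component values drawn from truncated Gaussians; and an
optional multiplicative *edge deficit* that depresses component values in
patch-edge cells, giving a known ground truth for edge-effect recovery.

Default class profiles are stylized rather than tied to any particular
city: class contrasts are strong, and the roadside class (young plantings
on reconstructed sandy fill) anchors each component's minimum near zero,
which keeps a multiplicative edge contrast identifiable after min-max
normalization.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .carbon import TreeInventory
from .grids import COMPONENT_NAMES, ComponentStack, GridRaster
from .landscape import detect_edges, label_patches

__all__ = [
    "ClassSpec",
    "LandscapeSpec",
    "default_spec",
    "generate_landcover",
    "generate_components",
    "generate_tree_inventory",
    "DEFAULT_ALLOMETRIC_COEFFICIENTS",
]

NODATA = -9999.0

#: Physical upper bounds per component (lower bound is always 0);
#: silt+clay is a percentage.
_UPPER_BOUNDS = {"soil_potential": 100.0}


@dataclass(frozen=True)
class ClassSpec:
    """One land-cover class of the synthetic mosaic.

    ``means``/``sds`` map component names to the class's truncated-Gaussian
    parameters; classes without components (impervious, water) leave them
    empty and come out nodata.
    """

    name: str
    code: int
    fraction: float
    n_seeds: int = 5
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class LandscapeSpec:
    """Full recipe for one synthetic landscape.

    ``edge_deficit`` multiplies component values in edge cells (1 = no
    deficit); a dict gives per-component factors.  Class fractions must sum
    to <= 1; the remainder becomes the background class (impervious).
    """

    shape: tuple[int, int] = (200, 200)
    cell_size: float = 30.0
    classes: tuple[ClassSpec, ...] = ()
    background_code: int = 6
    background_name: str = "impervious"
    edge_deficit: float | dict[str, float] = 1.0
    edge_distance_m: float = 30.0
    seed: int = 0
    roughness: float = 1.0

    def class_names(self) -> dict[int, str]:
        names = {c.code: c.name for c in self.classes}
        names[self.background_code] = self.background_name
        return names

    def vegetated_codes(self) -> list[int]:
        return [c.code for c in self.classes if c.means]

    def validate(self) -> None:
        total = sum(c.fraction for c in self.classes)
        if total > 1.0 + 1e-9:
            raise ValueError(f"class fractions sum to {total:.3f} > 1")
        if isinstance(self.edge_deficit, dict):
            deficits = self.edge_deficit.values()
        else:
            deficits = [self.edge_deficit]
        for d in deficits:
            if not 0 < d <= 1:
                raise ValueError(f"edge_deficit must be in (0, 1], got {d}")
        for c in self.classes:
            for sd in c.sds.values():
                if sd < 0:
                    raise ValueError(f"class {c.name}: sd must be >= 0")


# Stylized per-class component profiles (veg C and soil C in tC/ha, net
# uptake in tC/ha/yr, silt+clay in %).  Forest dominates every component;
# roadside fill soils anchor the minima near zero.
_DEFAULT_MEANS = {
    "forest": {"vegetation_c": 80.0, "soil_c": 45.0, "net_uptake": 10.0, "soil_potential": 35.0},
    "park": {"vegetation_c": 35.0, "soil_c": 30.0, "net_uptake": 5.0, "soil_potential": 30.0},
    "agricultural": {"vegetation_c": 8.0, "soil_c": 20.0, "net_uptake": 3.0, "soil_potential": 40.0},
    "roadside": {"vegetation_c": 5.0, "soil_c": 8.0, "net_uptake": 0.5, "soil_potential": 8.0},
}


def default_spec(
    seed: int = 0,
    shape: tuple[int, int] = (200, 200),
    edge_deficit: float | dict[str, float] = 1.0,
    noise: float = 0.05,
) -> LandscapeSpec:
    """The stock study landscape: five grown classes over an impervious
    background, with relative within-class noise ``noise`` (sd as a
    fraction of the class mean)."""
    fractions = {"forest": 0.30, "park": 0.15, "agricultural": 0.20,
                 "roadside": 0.05, "water": 0.05}
    seeds = {"forest": 4, "park": 10, "agricultural": 6, "roadside": 30, "water": 3}
    classes = []
    for code, name in enumerate(["forest", "park", "agricultural", "roadside", "water"], start=1):
        means = _DEFAULT_MEANS.get(name, {})
        sds = {comp: noise * mu for comp, mu in means.items()}
        classes.append(ClassSpec(name=name, code=code, fraction=fractions[name],
                                 n_seeds=seeds[name], means=means, sds=sds))
    return LandscapeSpec(shape=shape, classes=tuple(classes),
                         edge_deficit=edge_deficit, seed=seed)


def generate_landcover(spec: LandscapeSpec) -> GridRaster:
    """Seeded-region-growing mosaic approximating the class fractions.

    Each class grows from random seed cells through a jittered-priority
    flood fill until its cell budget (fraction x grid size) is met;
    unassigned cells become the background class.  Deterministic for a
    fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    n_cells = rows * cols
    grid = np.full(spec.shape, -1, dtype=np.int32)
    budgets = {c.code: int(round(c.fraction * n_cells)) for c in spec.classes}
    counts = {c.code: 0 for c in spec.classes}
    heap: list[tuple[float, int, int, int, int]] = []
    counter = 0
    order = rng.permutation(len(spec.classes))
    for ci in order:
        c = spec.classes[ci]
        if budgets[c.code] == 0:
            continue
        placed = 0
        while placed < c.n_seeds:
            r, ccol = int(rng.integers(rows)), int(rng.integers(cols))
            if grid[r, ccol] == -1:
                heapq.heappush(heap, (rng.random() * spec.roughness, counter, r, ccol, c.code))
                counter += 1
                placed += 1
    while heap:
        prio, _, r, c, code = heapq.heappop(heap)
        if grid[r, c] != -1 or counts[code] >= budgets[code]:
            continue
        grid[r, c] = code
        counts[code] += 1
        if counts[code] >= budgets[code]:
            continue
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols and grid[nr, nc] == -1:
                heapq.heappush(
                    heap, (prio + rng.random() * spec.roughness, counter, nr, nc, code)
                )
                counter += 1
    grid[grid == -1] = spec.background_code
    return GridRaster(values=grid.astype(np.uint8), cell_size=spec.cell_size,
                      nodata=None, categorical=True)


def generate_components(landcover: GridRaster, spec: LandscapeSpec) -> ComponentStack:
    """Per-class truncated-Gaussian component rasters with an edge deficit.

    Cells of classes without component profiles (impervious, water) are
    nodata.  Edge cells (within ``spec.edge_distance_m`` of a class
    boundary) have their values multiplied by the edge deficit after
    sampling.  Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    patches = detect_edges(label_patches(landcover), distance_m=spec.edge_distance_m)
    edge = patches.edge
    rasters = {}
    for comp in COMPONENT_NAMES:
        arr = np.full(landcover.shape, NODATA, dtype=np.float64)
        upper = _UPPER_BOUNDS.get(comp, np.inf)
        if isinstance(spec.edge_deficit, dict):
            deficit = spec.edge_deficit.get(comp, 1.0)
        else:
            deficit = spec.edge_deficit
        for c in spec.classes:
            if comp not in c.means:
                continue
            cells = landcover.values == c.code
            k = int(cells.sum())
            if k == 0:
                continue
            mu, sd = c.means[comp], c.sds.get(comp, 0.0)
            if sd == 0:
                vals = np.full(k, mu)
            else:
                a, b = (0.0 - mu) / sd, (upper - mu) / sd
                vals = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=k,
                                           random_state=rng)
            arr[cells] = vals
            arr[cells & edge] *= deficit
        rasters[comp] = landcover.with_values(
            arr, nodata=NODATA, categorical=False
        )
    return ComponentStack(**rasters)


#: Species-specific allometric coefficients (tC per tree from DBH in cm)
#: for common Korean urban street/park trees; stylized values in the range
#: reported for temperate broadleaf and conifer allometries.
DEFAULT_ALLOMETRIC_COEFFICIENTS = pd.DataFrame(
    {
        "a": [1.0e-4, 1.4e-4, 0.8e-4, 1.2e-4],
        "b": [2.45, 2.35, 2.50, 2.30],
    },
    index=pd.Index(
        ["Ginkgo biloba", "Prunus yedoensis", "Quercus acutissima", "Pinus densiflora"],
        name="species",
    ),
)


def generate_tree_inventory(
    n_trees: int,
    species_mix: dict[str, float] | None = None,
    dbh_lognormal_params: tuple[float, float] = (3.0, 0.35),
    seed: int = 0,
    coefficients: pd.DataFrame | None = None,
) -> TreeInventory:
    """Random street-tree inventory with lognormal DBH (cm).

    ``dbh_lognormal_params`` are the (mean, sd) of log DBH; the defaults
    centre around ~20 cm.  Reproducible for a fixed seed.
    """
    if coefficients is None:
        coefficients = DEFAULT_ALLOMETRIC_COEFFICIENTS
    if species_mix is None:
        species_mix = {sp: 1.0 / len(coefficients) for sp in coefficients.index}
    names = list(species_mix)
    probs = np.asarray([species_mix[s] for s in names], dtype=float)
    if n_trees > 0 and ((probs < 0).any() or probs.sum() <= 0):
        raise ValueError("species_mix must hold nonnegative weights with a positive sum")
    rng = np.random.default_rng(seed)
    if n_trees == 0:
        records = pd.DataFrame({"species": pd.Series(dtype=object),
                                "dbh_cm": pd.Series(dtype=float)})
        return TreeInventory(records=records, coefficients=coefficients)
    probs = probs / probs.sum()
    species = rng.choice(names, size=n_trees, p=probs)
    mu, sigma = dbh_lognormal_params
    dbh = rng.lognormal(mean=mu, sigma=sigma, size=n_trees)
    records = pd.DataFrame({"species": species, "dbh_cm": dbh})
    return TreeInventory(records=records, coefficients=coefficients)
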