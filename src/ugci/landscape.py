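"""Landscape analytics: patches, edges, adjacency, and edge-effect tests.

Patches are connected components of equal land-cover class (8-connected by
default).  A patch cell is an *edge* cell when its centre lies within a
stated distance (default 30 m) of the centre of any cell of a different
class or of nodata — at 30 m resolution this is the outermost one-cell
ring of each patch.  Edge cells are further classified by what they touch
(impervious, green, or both), and edge-vs-interior contrasts are tested
with Welch two-sample t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grids import GridRaster

__all__ = [
    "PatchMap",
    "ADJACENCY_NONE",
    "ADJACENCY_IMPERVIOUS",
    "ADJACENCY_GREEN",
    "ADJACENCY_MIXED",
    "label_patches",
    "detect_edges",
    "classify_adjacency",
    "zonal_stats",
    "compare_edge_interior",
    "patch_size_correlation",
]

ADJACENCY_NONE = 0
ADJACENCY_IMPERVIOUS = 1
ADJACENCY_GREEN = 2
ADJACENCY_MIXED = 3

_STRUCTURE_4 = ndimage.generate_binary_structure(2, 1)
_STRUCTURE_8 = ndimage.generate_binary_structure(2, 2)


@dataclass
class PatchMap:
    """Connected-component patches of a categorical land-cover raster.

    ``labels`` holds dense patch ids from 1 (0 = nodata background);
    ``patch_class`` maps each patch id to its land-cover code.  ``edge``
    and ``adjacency`` are filled by :func:`detect_edges` and
    :func:`classify_adjacency`.
    """

    labels: np.ndarray
    patch_class: dict[int, int]
    landcover: GridRaster
    connectivity: int
    edge: np.ndarray | None = field(default=None)
    adjacency: np.ndarray | None = field(default=None)

    @property
    def n_patches(self) -> int:
        return len(self.patch_class)

    def patch_areas(self) -> pd.DataFrame:
        """Per-patch cell count and area (m^2 and ha)."""
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        cell_area = self.landcover.cell_size**2
        return pd.DataFrame({
            "patch": ids.astype(int),
            "landcover_code": [self.patch_class[int(i)] for i in ids],
            "cells": counts.astype(int),
            "area_m2": counts * cell_area,
            "area_ha": counts * cell_area / 1e4,
        })

    def interior(self) -> np.ndarray:
        if self.edge is None:
            raise ValueError("edges not detected yet; call detect_edges first")
        return (self.labels > 0) & ~self.edge


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return _STRUCTURE_4
    if connectivity == 8:
        return _STRUCTURE_8
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def label_patches(landcover: GridRaster, connectivity: int = 8) -> PatchMap:
    """Label same-class connected components with dense ids from 1."""
    if not landcover.categorical:
        raise ValueError("label_patches requires a categorical raster")
    structure = _structure(connectivity)
    valid = landcover.mask
    labels = np.zeros(landcover.shape, dtype=np.int32)
    patch_class: dict[int, int] = {}
    next_id = 1
    for code in np.unique(landcover.values[valid]):
        class_mask = (landcover.values == code) & valid
        lab, n = ndimage.label(class_mask, structure=structure)
        labels[class_mask] = lab[class_mask] + (next_id - 1)
        for k in range(1, n + 1):
            patch_class[next_id - 1 + k] = int(code)
        next_id += n
    return PatchMap(labels=labels, patch_class=patch_class,
                    landcover=landcover, connectivity=connectivity)


def detect_edges(patches: PatchMap, distance_m: float = 30.0) -> PatchMap:
    """Flag patch cells within ``distance_m`` of a class boundary.

    Distance is Euclidean between cell centres; cells beyond the raster
    border count as nodata, so raster-margin cells are edges.  Fills
    ``patches.edge`` in place and returns the map.
    """
    lc = patches.landcover
    if distance_m < lc.cell_size:
        warnings.warn(
            f"distance_m={distance_m} is below the cell size {lc.cell_size}; "
            "no cell centre can be that close to a foreign cell centre",
            stacklevel=2,
        )
    r_cells = distance_m / lc.cell_size
    pad = int(np.floor(r_cells)) + 1
    valid = lc.mask
    edge = np.zeros(lc.shape, dtype=bool)
    for code in np.unique(lc.values[valid]):
        same = (lc.values == code) & valid
        # pad with "foreign" so the raster border behaves as nodata
        same_p = np.pad(same, pad, constant_values=False)
        dist = ndimage.distance_transform_edt(same_p)  # distance to nearest foreign cell centre
        edge |= same & (dist[pad:-pad, pad:-pad] * lc.cell_size <= distance_m)
    patches.edge = edge & (patches.labels > 0)
    return patches


def classify_adjacency(
    patches: PatchMap,
    impervious_classes: set[int],
    green_classes: set[int],
    connectivity: int | None = None,
) -> PatchMap:
    """Classify each edge cell by its out-of-class neighbourhood.

    Impervious-adjacent if some neighbour of a different class is
    impervious and none is green; green-adjacent for the converse; mixed
    otherwise (including edge cells whose only foreign contact is nodata
    or the raster border).  Fills ``patches.adjacency`` in place.
    """
    if not impervious_classes:
        raise ValueError("impervious_classes must not be empty")
    if patches.edge is None:
        raise ValueError("edges not detected yet; call detect_edges first")
    conn = connectivity if connectivity is not None else patches.connectivity
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    if conn == 4:
        offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    lc = patches.landcover
    valid = lc.mask
    has_imp = np.zeros(lc.shape, dtype=bool)
    has_green = np.zeros(lc.shape, dtype=bool)
    imp_arr = np.isin(lc.values, list(impervious_classes)) & valid
    green_arr = np.isin(lc.values, list(green_classes)) & valid
    lc_int = np.asarray(lc.values, dtype=np.int64)
    for dr, dc in offsets:
        nb_class = _shift(lc_int, dr, dc, fill=-1)
        nb_imp = _shift(imp_arr, dr, dc, fill=False)
        nb_green = _shift(green_arr, dr, dc, fill=False)
        foreign = nb_class != lc_int
        has_imp |= foreign & nb_imp
        has_green |= foreign & nb_green
    adjacency = np.zeros(lc.shape, dtype=np.uint8)
    e = patches.edge
    adjacency[e & has_imp & ~has_green] = ADJACENCY_IMPERVIOUS
    adjacency[e & has_green & ~has_imp] = ADJACENCY_GREEN
    adjacency[e & ~((has_imp & ~has_green) | (has_green & ~has_imp))] = ADJACENCY_MIXED
    patches.adjacency = adjacency
    return patches


def _shift(arr: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    out = np.full_like(arr, fill)
    rows, cols = arr.shape
    src_r = slice(max(0, -dr), min(rows, rows - dr))
    src_c = slice(max(0, -dc), min(cols, cols - dc))
    dst_r = slice(max(0, dr), min(rows, rows + dr))
    dst_c = slice(max(0, dc), min(cols, cols + dc))
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def zonal_stats(values: GridRaster, zones: GridRaster) -> pd.DataFrame:
    """Mean, sample sd, and count of valid values per zone.

    Zones that are entirely nodata in either raster are omitted; a
    single-cell zone reports sd 0 with ``sd_defined = False``.
    """
    if values.shape != zones.shape:
        raise ValueError(
            f"value and zone rasters are not aligned: {values.shape} vs {zones.shape}"
        )
    ok = values.mask & zones.mask
    if not ok.any():
        return pd.DataFrame(columns=["zone", "mean", "sd", "n", "sd_defined"])
    df = pd.DataFrame({
        "zone": np.asarray(zones.values)[ok],
        "value": np.asarray(values.values, dtype=float)[ok],
    })
    g = df.groupby("zone")["value"]
    out = pd.DataFrame({
        "zone": g.mean().index,
        "mean": g.mean().to_numpy(),
        "sd": g.std(ddof=1).to_numpy(),
        "n": g.count().to_numpy(),
    }).reset_index(drop=True)
    out["sd_defined"] = out["n"] > 1
    out.loc[~out["sd_defined"], "sd"] = 0.0
    return out


def compare_edge_interior(
    values: GridRaster | np.ndarray,
    patches: PatchMap,
    by_class: list[int] | None = None,
    class_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Edge-vs-interior contrast of a value surface, per land-cover class.

    For each class: mean value over edge and interior cells of its patches,
    the edge deficit ``100 * (interior - edge) / interior`` (percent lower
    at the edge), and a Welch two-sample t-test.  Classes with fewer than
    two cells on either side are skipped with a notice row
    (``skipped = True``).  ``values`` is typically the UGCI surface but any
    aligned raster works.
    """
    if patches.edge is None:
        raise ValueError("edges not detected yet; call detect_edges first")
    arr = values.values if isinstance(values, GridRaster) else np.asarray(values)
    arr = np.asarray(arr, dtype=float)
    if arr.shape != patches.labels.shape:
        raise ValueError("value surface is not aligned with the patch map")
    vmask = values.mask if isinstance(values, GridRaster) else np.isfinite(arr)
    lc = patches.landcover
    codes = by_class if by_class is not None else sorted(
        set(patches.patch_class.values())
    )
    interior = patches.interior()
    rows = []
    for code in codes:
        in_class = (lc.values == code) & (patches.labels > 0)
        e = arr[in_class & patches.edge & vmask]
        i = arr[in_class & interior & vmask]
        name = class_names.get(code, str(code)) if class_names else str(code)
        if len(e) < 2 or len(i) < 2:
            warnings.warn(
                f"class {name}: fewer than 2 edge or interior cells; skipped",
                stacklevel=2,
            )
            rows.append({
                "landcover_code": code, "landcover": name,
                "n_edge": len(e), "n_interior": len(i),
                "edge_mean": np.nan, "interior_mean": np.nan,
                "pct_lower": np.nan, "t": np.nan, "p": np.nan, "skipped": True,
            })
            continue
        t, p = stats.ttest_ind(e, i, equal_var=False)
        interior_mean = float(i.mean())
        edge_mean = float(e.mean())
        pct = 100.0 * (interior_mean - edge_mean) / interior_mean
        rows.append({
            "landcover_code": code, "landcover": name,
            "n_edge": len(e), "n_interior": len(i),
            "edge_mean": edge_mean, "interior_mean": interior_mean,
            "pct_lower": pct, "t": float(t), "p": float(p), "skipped": False,
        })
    return pd.DataFrame(rows)


def patch_size_correlation(
    values: GridRaster | np.ndarray,
    patches: PatchMap,
    landcover_code: int,
) -> tuple[float, float]:
    """Pearson correlation of log patch area vs per-patch mean value.

    Requires at least three patches of the class; returns ``(nan, nan)``
    when areas or patch means are constant (correlation undefined).
    """
    arr = values.values if isinstance(values, GridRaster) else np.asarray(values)
    arr = np.asarray(arr, dtype=float)
    vmask = values.mask if isinstance(values, GridRaster) else np.isfinite(arr)
    ids = [pid for pid, code in patches.patch_class.items() if code == landcover_code]
    if len(ids) < 3:
        raise ValueError(
            f"patch-size correlation needs >= 3 patches of class {landcover_code}, "
            f"got {len(ids)}"
        )
    areas, means = [], []
    cell_area_ha = patches.landcover.cell_size**2 / 1e4
    for pid in ids:
        cells = patches.labels == pid
        areas.append(cells.sum() * cell_area_ha)
        vals = arr[cells & vmask]
        means.append(vals.mean() if len(vals) else np.nan)
    areas = np.asarray(areas, dtype=float)
    means = np.asarray(means, dtype=float)
    ok = np.isfinite(means)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 patches with valid values")
    areas, means = areas[ok], means[ok]
    if np.ptp(areas) == 0 or np.ptp(means) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(np.log(areas), means)
    return float(r), float(p)
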