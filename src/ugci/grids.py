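"""Grid rasters, GeoTIFF I/O, and the two regridding contracts.

All analysis layers live on axis-aligned square grids indexed row-major
from the top-left corner; a cell is identified with its centre, and all
distances are metres derived from ``cell_size``.  Continuous layers are
stored as float32 GeoTIFFs, categorical layers as uint8 with a class-code
map kept in the run configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "GridRaster",
    "ComponentStack",
    "COMPONENT_NAMES",
    "read_raster",
    "write_raster",
    "aggregate_dominant",
    "resample_bilinear",
    "stack_components",
]

#: Canonical order of the four index components.
COMPONENT_NAMES = ("vegetation_c", "soil_c", "net_uptake", "soil_potential")

# GeoTIFF / GDAL tag codes used for georeferencing round-trips.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids: model type (1 = projected, 2 = geographic) and the EPSG code
# slots for each model type.
_KEY_MODEL_TYPE = 1024
_KEY_GEOGRAPHIC_CS = 2048
_KEY_PROJECTED_CS = 3072


@dataclass
class GridRaster:
    """A single-band raster on a square, axis-aligned grid.

    Parameters
    ----------
    values:
        2-D array (rows, cols); rows increase southwards.
    cell_size:
        Cell edge length in metres (> 0).
    origin:
        World coordinates ``(x, y)`` of the outer corner of cell (0, 0)
        (top-left corner of the raster).
    crs:
        CRS identifier as ``"EPSG:<code>"``.
    nodata:
        Sentinel marking invalid cells, or ``None`` when every cell is valid.
    categorical:
        Whether values are class codes (no interpolation allowed).
    """

    values: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "EPSG:32652"
    nodata: float | int | None = None
    categorical: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got {self.values.ndim}-D")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        valid = np.ones(self.values.shape, dtype=bool)
        if self.nodata is not None:
            valid &= self.values != self.nodata
        if np.issubdtype(self.values.dtype, np.floating):
            valid &= np.isfinite(self.values)
        return valid

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates (x, y) of every cell centre."""
        rows, cols = np.indices(self.shape)
        x = self.origin[0] + (cols + 0.5) * self.cell_size
        y = self.origin[1] - (rows + 0.5) * self.cell_size
        return x, y

    def same_geometry(self, other: "GridRaster", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size, rel_tol=rtol)
            and math.isclose(self.origin[0], other.origin[0], rel_tol=rtol, abs_tol=1e-6)
            and math.isclose(self.origin[1], other.origin[1], rel_tol=rtol, abs_tol=1e-6)
            and self.crs == other.crs
        )

    def with_values(self, values: np.ndarray, **kwargs) -> "GridRaster":
        """New raster sharing this geometry with replaced values."""
        out = replace(self, values=np.asarray(values))
        for k, v in kwargs.items():
            setattr(out, k, v)
        return out


def _epsg_code(crs: str) -> int:
    try:
        authority, code = crs.split(":")
    except ValueError:
        raise ValueError(f"CRS must look like 'EPSG:32652', got {crs!r}") from None
    if authority.upper() != "EPSG":
        raise ValueError(f"only EPSG CRS identifiers are supported, got {crs!r}")
    return int(code)


def write_raster(path: str | Path, raster: GridRaster) -> None:
    """Write a :class:`GridRaster` as a single-band GeoTIFF."""
    path = Path(path)
    code = _epsg_code(raster.crs)
    # Geographic CRSs use EPSG codes < 32767 in the 4xxx range; treat 4xxx as
    # geographic, everything else as projected.  Only the round-trip matters.
    geographic = 4000 <= code < 5000
    key_id = _KEY_GEOGRAPHIC_CS if geographic else _KEY_PROJECTED_CS
    geokeys = [
        1, 1, 0, 2,
        _KEY_MODEL_TYPE, 0, 1, 2 if geographic else 1,
        key_id, 0, 1, code,
    ]
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (raster.cell_size, raster.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, raster.origin[0], raster.origin[1], 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), tuple(geokeys)),
    ]
    if raster.nodata is not None:
        nodata_str = repr(raster.nodata)
        extratags.append((_TAG_GDAL_NODATA, "s", len(nodata_str), nodata_str))
    values = raster.values
    if not raster.categorical and values.dtype != np.float32 and np.issubdtype(
        values.dtype, np.floating
    ):
        values = values.astype(np.float32)
    tifffile.imwrite(path, values, extratags=extratags)


def read_raster(
    path: str | Path, band: int = 0, categorical: bool = False
) -> GridRaster:
    """Read one band of a GeoTIFF into a :class:`GridRaster`.

    Raises
    ------
    ValueError
        If the file is not a readable TIFF or carries no CRS geokeys.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:  # noqa: BLE001 - normalise format errors
        raise ValueError(f"{path} is not a readable GeoTIFF: {exc}") from exc
    with tif:
        if band >= len(tif.pages):
            raise ValueError(f"{path} has {len(tif.pages)} band(s); band {band} requested")
        page = tif.pages[band]
        values = page.asarray()
        tags = page.tags
        if _TAG_GEO_KEY_DIRECTORY not in tags:
            raise ValueError(f"{path} has no coordinate reference system (GeoKey directory missing)")
        geokeys = tags[_TAG_GEO_KEY_DIRECTORY].value
        crs = _crs_from_geokeys(geokeys, path)
        if _TAG_MODEL_PIXEL_SCALE in tags:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            cell_size = float(scale[0])
        else:
            cell_size = 30.0
        if _TAG_MODEL_TIEPOINT in tags:
            tp = tags[_TAG_MODEL_TIEPOINT].value
            origin = (float(tp[3]), float(tp[4]))
        else:
            origin = (0.0, 0.0)
        nodata: float | int | None = None
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value
            nodata = float(raw)
            if np.issubdtype(values.dtype, np.integer):
                nodata = int(nodata)
    return GridRaster(
        values=values,
        cell_size=cell_size,
        origin=origin,
        crs=crs,
        nodata=nodata,
        categorical=categorical,
    )


def _crs_from_geokeys(geokeys, path: Path) -> str:
    keys = np.asarray(geokeys).ravel()
    # entries of four shorts each, after the 4-short header
    for i in range(4, len(keys) - 3, 4):
        key_id, _, _, value = keys[i : i + 4]
        if key_id in (_KEY_PROJECTED_CS, _KEY_GEOGRAPHIC_CS):
            return f"EPSG:{int(value)}"
    raise ValueError(f"{path} has no EPSG code in its GeoKey directory")


def aggregate_dominant(fine: GridRaster, factor: int) -> GridRaster:
    """Aggregate a categorical raster by taking the modal class per block.

    Each coarse cell covers a ``factor x factor`` block of fine cells and
    takes the most frequent class among the valid fine cells; ties break to
    the smallest class code, and all-nodata blocks stay nodata.  Rasters
    whose dimensions are not divisible by ``factor`` are padded with nodata
    on the bottom/right before blocking.
    """
    if not fine.categorical:
        raise ValueError("aggregate_dominant requires a categorical raster")
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    nodata = fine.nodata if fine.nodata is not None else np.iinfo(np.int64).min
    rows, cols = fine.shape
    out_rows = math.ceil(rows / factor)
    out_cols = math.ceil(cols / factor)
    padded = np.full((out_rows * factor, out_cols * factor), nodata,
                     dtype=np.int64)
    padded[:rows, :cols] = fine.values
    if fine.nodata is None:
        valid_pad = np.zeros(padded.shape, dtype=bool)
        valid_pad[:rows, :cols] = True
    else:
        valid_pad = padded != nodata
    blocks = padded.reshape(out_rows, factor, out_cols, factor)
    vmask = valid_pad.reshape(out_rows, factor, out_cols, factor)
    out = np.full((out_rows, out_cols), nodata, dtype=np.int64)
    for r in range(out_rows):
        for c in range(out_cols):
            vals = blocks[r, :, c, :][vmask[r, :, c, :]]
            if vals.size == 0:
                continue
            codes, counts = np.unique(vals, return_counts=True)
            out[r, c] = codes[np.argmax(counts)]  # unique is sorted: ties -> smallest code
    out_nodata = fine.nodata if fine.nodata is not None else nodata
    out_arr = out.astype(fine.values.dtype) if fine.nodata is not None else out
    return GridRaster(
        values=out_arr,
        cell_size=fine.cell_size * factor,
        origin=fine.origin,
        crs=fine.crs,
        nodata=out_nodata if (valid_pad.sum() < padded.size or fine.nodata is not None) else None,
        categorical=True,
    )


def resample_bilinear(coarse: GridRaster, target: GridRaster) -> GridRaster:
    """Resample a continuous raster onto the geometry of ``target``.

    Values are bilinear interpolations between coarse cell centres.  Target
    cells outside the convex support of the coarse centres, and coarse
    nodata holes, take the nearest valid coarse value (clamping keeps the
    output inside the coarse value range).
    """
    if coarse.categorical:
        raise ValueError("resample_bilinear requires a continuous raster")
    valid = coarse.mask
    if not valid.any():
        raise ValueError("coarse raster has no valid cells")
    filled = np.asarray(coarse.values, dtype=np.float64)
    if not valid.all():
        # replace nodata holes with their nearest valid neighbour
        idx = ndimage.distance_transform_edt(
            ~valid, return_distances=False, return_indices=True
        )
        filled = filled[tuple(idx)]
    tx, ty = target.cell_centers()
    # fractional index of target centres in the coarse grid
    col = (tx - coarse.origin[0]) / coarse.cell_size - 0.5
    row = (coarse.origin[1] - ty) / coarse.cell_size - 0.5
    out = ndimage.map_coordinates(
        filled, [row, col], order=1, mode="nearest"
    )
    return GridRaster(
        values=out.astype(np.float64),
        cell_size=target.cell_size,
        origin=target.origin,
        crs=target.crs,
        nodata=None,
        categorical=False,
    )


@dataclass
class ComponentStack:
    """The four co-registered component rasters behind the index.

    The validity mask is the intersection of per-component validity: a cell
    with nodata in any component is excluded from every downstream statistic.
    """

    vegetation_c: GridRaster
    soil_c: GridRaster
    net_uptake: GridRaster
    soil_potential: GridRaster
    mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ref = self.vegetation_c
        for name in COMPONENT_NAMES[1:]:
            raster = getattr(self, name)
            if not ref.same_geometry(raster):
                raise ValueError(
                    f"component raster {name!r} does not share the stack geometry "
                    f"(shape {raster.shape} vs {ref.shape}, "
                    f"cell {raster.cell_size} vs {ref.cell_size})"
                )
        mask = ref.mask
        for name in COMPONENT_NAMES[1:]:
            mask = mask & getattr(self, name).mask
        self.mask = mask

    def __iter__(self) -> Iterator[GridRaster]:
        return (getattr(self, name) for name in COMPONENT_NAMES)

    @property
    def n(self) -> int:
        """Number of valid grid cells."""
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.vegetation_c.shape

    @property
    def cell_size(self) -> float:
        return self.vegetation_c.cell_size

    def matrix(self) -> np.ndarray:
        """(n, 4) array of raw component values over valid cells.

        Row order follows row-major order of the valid cells; columns follow
        :data:`COMPONENT_NAMES`.
        """
        return np.column_stack(
            [np.asarray(getattr(self, name).values, dtype=float)[self.mask]
             for name in COMPONENT_NAMES]
        )

    def valid_indices(self) -> np.ndarray:
        """(n, 2) array of (row, col) indices of valid cells, row-major."""
        return np.argwhere(self.mask)


def stack_components(
    vegetation_c: GridRaster,
    soil_c: GridRaster,
    net_uptake: GridRaster,
    soil_potential: GridRaster,
) -> ComponentStack:
    """Assemble the four component rasters into a validated stack."""
    return ComponentStack(vegetation_c, soil_c, net_uptake, soil_potential)
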