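"""Raster I/O: ESRI ASCII grids and single-band (Geo)TIFF.

Nodata cells in an input file become ``mask=False`` pixels; masked pixels
are written back out as the nodata value.  Negative finite values are a
domain violation (scores and populations are non-negative) and are rejected
with the offending cell named.

The ASCII writer uses ``%.17g`` formatting so a read/write round-trip is
bit-exact for finite float64 cells.  TIFF support uses :mod:`tifffile`
with the GDAL_NODATA, ModelPixelScale and ModelTiepoint tags, which is
enough geometry for the planar grids this package works on (CRS metadata
is passed through, never computed on).
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING

import numpy as np

from .grids import ContextGrid, GridSpec

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import MetricSurface

__all__ = ["read_grid", "write_grid", "DEFAULT_NODATA"]

DEFAULT_NODATA = -9999.0

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridValidationError(ValueError):
    """Raised when a raster violates the grid domain contract."""


def _is_tiff(path: str) -> bool:
    return os.path.splitext(path)[1].lower() in (".tif", ".tiff")


def read_grid(
    path: str,
    band_semantics: str = "toxicity",
    nodata: float | None = None,
    year: int = 0,
) -> ContextGrid:
    """Read a single-band raster into a :class:`ContextGrid`.

    Parameters
    ----------
    path
        ESRI ASCII grid (``.asc``/``.grd``/anything non-TIFF) or
        single-band TIFF (``.tif``/``.tiff``).
    band_semantics
        ``"toxicity"`` or ``"population"`` — which field of the returned
        grid the band fills (the other is left unset/constant).
    nodata
        Override for the file's declared nodata value; required if the file
        declares none.
    year
        Year stamp for the returned grid.
    """
    if band_semantics not in ("toxicity", "population"):
        raise ValueError(f"unknown band_semantics {band_semantics!r}")
    if _is_tiff(path):
        values, spec, file_nodata = _read_tiff(path)
    else:
        values, spec, file_nodata = _read_esri_ascii(path)
    if nodata is None:
        nodata = file_nodata
    mask = np.isfinite(values)
    if nodata is not None:
        mask &= values != nodata
    bad = mask & np.isfinite(values) & (values < 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise GridValidationError(
            f"{path}: negative value {values[r, c]} at cell ({r}, {c})"
        )
    clean = np.where(mask, values, 0.0)
    if band_semantics == "population":
        return ContextGrid(
            spec=spec,
            toxicity=np.zeros(spec.shape),
            population=clean,
            mask=mask,
            year=year,
        )
    return ContextGrid(spec=spec, toxicity=clean, mask=mask, year=year)


def _read_esri_ascii(path: str):
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "xllcenter",
                "yllcenter",
                "cellsize",
                "nodata_value",
                "dx",
                "dy",
            ):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows"):
        if req not in header:
            raise GridValidationError(f"{path}: missing ESRI ASCII header {req}")
    if "cellsize" in header:
        cellsize = header["cellsize"]
    elif "dx" in header and "dy" in header:
        if header["dx"] != header["dy"]:
            raise GridValidationError(
                f"{path}: non-square pixels (dx={header['dx']}, dy={header['dy']})"
            )
        cellsize = header["dx"]
    else:
        raise GridValidationError(f"{path}: missing cellsize")
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cellsize / 2
    else:
        raise GridValidationError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cellsize / 2
    else:
        raise GridValidationError(f"{path}: missing yllcorner/yllcenter")
    values = np.loadtxt(data_lines, dtype=float, ndmin=2)
    if values.shape != (n_rows, n_cols):
        raise GridValidationError(
            f"{path}: data block shape {values.shape} != header "
            f"({n_rows}, {n_cols})"
        )
    # ESRI ASCII rows run north to south, matching row 0 = northernmost.
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        pixel_size=cellsize,
        origin_x=xll,
        origin_y=yll + n_rows * cellsize,
    )
    nodata = header.get("nodata_value")
    return values, spec, nodata


def _read_tiff(path: str):
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise GridValidationError(f"{path}: expected a single-band raster")
        tags = page.tags
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value if _TAG_MODEL_PIXEL_SCALE in tags else None
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value if _TAG_MODEL_TIEPOINT in tags else None
    if scale is not None:
        sx, sy = float(scale[0]), float(scale[1])
        if not np.isclose(sx, sy):
            raise GridValidationError(
                f"{path}: non-square pixels ({sx} x {sy})"
            )
        pixel_size = sx
    else:
        pixel_size = 1.0
    if tiepoint is not None:
        # raster point (i, j, k) -> model point (x, y, z); anchor at (0, 0)
        origin_x = float(tiepoint[3]) - float(tiepoint[0]) * pixel_size
        origin_y = float(tiepoint[4]) + float(tiepoint[1]) * pixel_size
    else:
        origin_x, origin_y = 0.0, 0.0
    spec = GridSpec(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        pixel_size=pixel_size,
        origin_x=origin_x,
        origin_y=origin_y,
    )
    return values, spec, nodata


def write_grid(
    grid: "ContextGrid | MetricSurface",
    path: str,
    band: str = "values",
    nodata: float = DEFAULT_NODATA,
) -> None:
    """Write a grid or metric surface as a single-band raster.

    For a :class:`ContextGrid`, ``band`` selects ``"toxicity"`` or
    ``"population"``; for a metric surface, ``"values"`` (default) or
    ``"bin"``.  Masked and undefined cells are written as ``nodata``.
    """
    if not path:
        raise ValueError("empty output path")
    from .metrics import MetricSurface

    if isinstance(grid, MetricSurface):
        spec = grid.spec
        if band == "bin":
            if grid.bin is None:
                raise ValueError("surface has no bin field; run bin_metric first")
            values = grid.bin.astype(float)
            invalid = grid.undefined | ~grid.defined_mask
        else:
            values = grid.values
            invalid = grid.undefined | ~grid.defined_mask
    elif isinstance(grid, ContextGrid):
        spec = grid.spec
        if band in ("values", "toxicity"):
            values = grid.toxicity
        elif band == "population":
            if grid.population is None:
                raise ValueError("grid has no population band")
            values = grid.population
        else:
            raise ValueError(f"unknown band {band!r}")
        invalid = ~grid.mask
    else:
        raise TypeError(f"cannot write object of type {type(grid).__name__}")

    out = np.where(invalid | ~np.isfinite(values), nodata, values)
    if _is_tiff(path):
        _write_tiff(out, spec, path, nodata)
    else:
        _write_esri_ascii(out, spec, path, nodata)


def _write_esri_ascii(values: np.ndarray, spec: GridSpec, path: str, nodata: float):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.origin_x:.17g}\n")
        fh.write(f"yllcorner {spec.y_min:.17g}\n")
        fh.write(f"cellsize {spec.pixel_size:.17g}\n")
        fh.write(f"NODATA_value {nodata:.17g}\n")
        for row in values:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def _write_tiff(values: np.ndarray, spec: GridSpec, path: str, nodata: float):
    import tifffile

    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (spec.pixel_size, spec.pixel_size, 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0),
        ),
        (_TAG_GDAL_NODATA, "s", 0, f"{nodata:.17g}"),
    ]
    tifffile.imwrite(path, values.astype(np.float64), extratags=extratags)
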