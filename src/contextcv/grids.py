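"""Regular square grid data model and point-to-pixel assignment.

The grid convention throughout the package:

* 0-based ``(row, col)`` indexing, row 0 is the **northernmost** row;
* ``(origin_x, origin_y)`` is the outer (north-west) corner of pixel
  ``(0, 0)``, so y decreases as the row index increases;
* cell membership is half-open: a point on a shared vertical edge belongs
  to the cell on its **east** side, a point on a shared horizontal edge to
  the cell **south** of it;
* coordinates are projected planar, in the same length units as
  ``pixel_size``; all distances are Euclidean in those units.

Masked-out pixels (``mask == False``) are outside the study region and are
excluded from every downstream statistic — they are never treated as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "GridSpec",
    "ContextGrid",
    "YearStack",
    "OUT_OF_GRID",
    "point_to_pixel",
    "points_to_pixels",
    "pixel_centers",
]

#: sentinel (row, col) returned for points outside the grid extent
OUT_OF_GRID: tuple[int, int] = (-1, -1)

#: half-mile RSEI-style pixel, in kilometres
DEFAULT_PIXEL_SIZE_KM = 0.805


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular square grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; at least 1 each.
    pixel_size
        Side length of a (square) pixel, in coordinate units.
        Defaults to 0.805 km (0.5 mi).
    origin_x, origin_y
        Coordinate of the outer north-west corner of pixel ``(0, 0)``.
    """

    n_rows: int
    n_cols: int
    pixel_size: float = DEFAULT_PIXEL_SIZE_KM
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(
                f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}"
            )
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def x_max(self) -> float:
        return self.origin_x + self.n_cols * self.pixel_size

    @property
    def y_min(self) -> float:
        return self.origin_y - self.n_rows * self.pixel_size


def point_to_pixel(x: float, y: float, spec: GridSpec) -> tuple[int, int]:
    """Assign a point to the pixel it falls in, or :data:`OUT_OF_GRID`.

    Membership is half-open: ``[edge, edge + pixel_size)`` in x, and
    ``(edge - pixel_size, edge]`` moving south in y, so a point exactly on
    the grid's north or west outer edge is inside, while one on the south
    or east outer edge is not.  Points outside the extent return
    :data:`OUT_OF_GRID` — never a clamped index.
    """
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError(f"non-finite coordinates ({x}, {y})")
    col = int(np.floor((x - spec.origin_x) / spec.pixel_size))
    row = int(np.floor((spec.origin_y - y) / spec.pixel_size))
    if 0 <= row < spec.n_rows and 0 <= col < spec.n_cols:
        return (row, col)
    return OUT_OF_GRID


def points_to_pixels(
    x: np.ndarray, y: np.ndarray, spec: GridSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`point_to_pixel`.

    Returns ``(rows, cols, inside)``; rows/cols are -1 where ``inside`` is
    False.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite coordinates in input")
    col = np.floor((x - spec.origin_x) / spec.pixel_size).astype(int)
    row = np.floor((spec.origin_y - y) / spec.pixel_size).astype(int)
    inside = (row >= 0) & (row < spec.n_rows) & (col >= 0) & (col < spec.n_cols)
    row = np.where(inside, row, -1)
    col = np.where(inside, col, -1)
    return row, col, inside


def pixel_centers(spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Center coordinates of every pixel as ``(X, Y)`` arrays of grid shape."""
    cols = np.arange(spec.n_cols)
    rows = np.arange(spec.n_rows)
    cx = spec.origin_x + (cols + 0.5) * spec.pixel_size
    cy = spec.origin_y - (rows + 0.5) * spec.pixel_size
    return np.meshgrid(cx, cy)


@dataclass
class ContextGrid:
    """One year of gridded context data (toxicity scores, optional population).

    ``toxicity`` holds a non-negative unitless score per pixel (RSEI-style);
    ``population`` an optional non-negative resident count per pixel;
    ``mask`` is True for pixels inside the study region.  Values at masked
    (False) pixels carry no meaning.
    """

    spec: GridSpec
    toxicity: np.ndarray
    year: int = 0
    population: np.ndarray | None = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.toxicity = np.asarray(self.toxicity, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.spec.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.toxicity.shape != self.spec.shape:
            raise ValueError(
                f"toxicity shape {self.toxicity.shape} != grid {self.spec.shape}"
            )
        if self.mask.shape != self.spec.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != grid {self.spec.shape}"
            )
        bad = self.mask & ~(self.toxicity >= 0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"negative or non-finite toxicity at pixel ({r}, {c}): "
                f"{self.toxicity[r, c]}"
            )
        if self.population is not None:
            self.population = np.asarray(self.population, dtype=float)
            if self.population.shape != self.spec.shape:
                raise ValueError(
                    f"population shape {self.population.shape} != grid "
                    f"{self.spec.shape}"
                )
            badp = self.mask & ~(self.population >= 0)
            if badp.any():
                r, c = np.argwhere(badp)[0]
                raise ValueError(
                    f"negative or non-finite population at pixel ({r}, {c}): "
                    f"{self.population[r, c]}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.spec.shape

    def masked_toxicity(self) -> np.ndarray:
        """Toxicity with masked-out pixels set to NaN."""
        out = self.toxicity.astype(float).copy()
        out[~self.mask] = np.nan
        return out


@dataclass
class YearStack:
    """An ordered multi-year sequence of :class:`ContextGrid` on one grid.

    All grids must share an identical :class:`GridSpec` and mask, and years
    must be strictly increasing.
    """

    grids: list[ContextGrid]

    def __post_init__(self) -> None:
        if len(self.grids) < 1:
            raise ValueError("YearStack needs at least one grid")
        spec0 = self.grids[0].spec
        mask0 = self.grids[0].mask
        years = [g.year for g in self.grids]
        for g in self.grids[1:]:
            if g.spec != spec0:
                raise ValueError("all grids in a YearStack must share one GridSpec")
            if not np.array_equal(g.mask, mask0):
                raise ValueError("all grids in a YearStack must share one mask")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError(f"years must be strictly increasing, got {years}")

    @property
    def spec(self) -> GridSpec:
        return self.grids[0].spec

    @property
    def mask(self) -> np.ndarray:
        return self.grids[0].mask

    @property
    def years(self) -> list[int]:
        return [g.year for g in self.grids]

    def __len__(self) -> int:
        return len(self.grids)

    def __iter__(self) -> Iterator[ContextGrid]:
        return iter(self.grids)

    def __getitem__(self, i: int) -> ContextGrid:
        return self.grids[i]

    def by_year(self, year: int) -> ContextGrid:
        for g in self.grids:
            if g.year == year:
                return g
        raise KeyError(f"year {year} not in stack (have {self.years})")

    def has_year(self, year: int) -> bool:
        return year in self.years

    def toxicity_cube(self) -> np.ndarray:
        """All years stacked as an ``(n_years, n_rows, n_cols)`` array."""
        return np.stack([g.toxicity for g in self.grids], axis=0)
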