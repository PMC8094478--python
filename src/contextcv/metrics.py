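"""Per-pixel uncertainty metrics for gridded contextual data.

Three coefficient-of-variation style statistics quantify how sensitive a
point-to-pixel linkage is to different sources of spatio-temporal
uncertainty:

* **PCV** (positional): SD of a pixel and its immediate neighbours divided
  by the pixel's own value.  High PCV means a small geolocation error
  could change the assigned contextual value a lot.
* **NCV** (neighbourhood size): SD of the mean value over nested square
  neighbourhoods of increasing size, divided by the pixel value.  High NCV
  means results depend on the analyst's choice of "neighbourhood" extent.
* **LCV** (life course): temporal SD of a pixel's value across years
  divided by its temporal median.  High LCV means the year chosen for a
  cross-sectional linkage matters.

All standard deviations are population SDs (divide by the member count,
not count − 1): the metrics are descriptive, and this keeps one- and
two-member windows well defined.  Pass ``ddof=1`` to any surface function
to get sample SDs instead.

Windows truncate at grid edges and at masked-out pixels — statistics are
taken over the available members only, never zero-filled.  Pixels whose
denominator is zero are *undefined*: a distinct state propagated through
binning, summaries and raster nodata, not an error.

All three metrics are invariant under rescaling the grid (``c * grid``
gives identical surfaces for ``c > 0``) but **not** under adding a
constant, since the denominator shifts while the SD does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import ContextGrid, GridSpec, YearStack

__all__ = [
    "NeighborhoodSpec",
    "BinScheme",
    "MetricSurface",
    "focal_sd",
    "focal_mean",
    "pcv_surface",
    "ncv_surface",
    "lcv_surface",
    "bin_metric",
]


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Nested square neighbourhoods given by window half-widths.

    The default ``(0, 1, 2, 3, 4, 9)`` yields square neighbourhoods of
    1, 9 (3x3), 25 (5x5), 49 (7x7), 81 (9x9) and 361 (19x19) pixels.
    Half-width 0 (the singleton pixel) must be present: its mean is the
    NCV denominator.
    """

    half_widths: tuple[int, ...] = (0, 1, 2, 3, 4, 9)

    def __post_init__(self) -> None:
        hw = self.half_widths
        if len(hw) == 0:
            raise ValueError("need at least one half-width")
        if any(h < 0 for h in hw):
            raise ValueError(f"half-widths must be non-negative: {hw}")
        if any(b <= a for a, b in zip(hw, hw[1:])):
            raise ValueError(f"half-widths must be strictly increasing: {hw}")
        if hw[0] != 0:
            raise ValueError("half-widths must include 0 (the singleton pixel)")

    @property
    def sizes(self) -> tuple[int, ...]:
        """Full pixel counts of the (untruncated) windows."""
        return tuple((2 * h + 1) ** 2 for h in self.half_widths)


@dataclass(frozen=True)
class BinScheme:
    """Shared classification bins for metric surfaces.

    Six left-closed right-open intervals: ``[0, e1), [e1, e2), ...,
    [e5, inf)`` labelled 1..6.  The defaults put very low / low uncertainty
    below 0.05, moderate below 0.075, and everything from 5 up in the top
    bin.
    """

    edges: tuple[float, ...] = (0.025, 0.05, 0.075, 0.5, 5.0)

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) == 0 or any(x <= 0 for x in e):
            raise ValueError(f"bin edges must be positive: {e}")
        if any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError(f"bin edges must be strictly increasing: {e}")

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def intervals(self) -> list[tuple[float, float]]:
        lo = (0.0,) + self.edges
        hi = self.edges + (np.inf,)
        return list(zip(lo, hi))

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin labels 1..n_bins for an array of non-negative values."""
        return np.digitize(values, self.edges, right=False) + 1


@dataclass
class MetricSurface:
    """Per-pixel values of one uncertainty metric.

    ``values`` is NaN wherever the metric is not defined — outside the
    study-region mask, or where ``undefined`` is True (zero denominator).
    ``bin`` (after :func:`bin_metric`) holds labels 1..6, with 0 at
    undefined/masked pixels.
    """

    spec: GridSpec
    metric: str
    values: np.ndarray
    undefined: np.ndarray
    mask: np.ndarray
    bin: np.ndarray | None = None
    scheme: BinScheme | None = None

    def __post_init__(self) -> None:
        for name in ("values", "undefined", "mask"):
            arr = getattr(self, name)
            if arr.shape != self.spec.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.spec.shape}")
        ok = self.defined_mask
        if not (self.values[ok] >= 0).all():
            raise ValueError(f"{self.metric} has negative defined values")

    @property
    def defined_mask(self) -> np.ndarray:
        """True where the metric has a finite, defined value."""
        return self.mask & ~self.undefined

    def defined_values(self) -> np.ndarray:
        """Flat vector of the defined metric values."""
        return self.values[self.defined_mask]


def _window_sums(arr: np.ndarray, half_width: int) -> np.ndarray:
    """Sum of ``arr`` over the (2h+1)^2 window at each pixel, zero-filled."""
    w = 2 * half_width + 1
    return ndimage.correlate(arr, np.ones((w, w)), mode="constant", cval=0.0)


def _focal_moments(grid: ContextGrid, half_width: int):
    """Member count, mean and population SD of each truncated focal window."""
    if half_width < 0:
        raise ValueError(f"half_width must be >= 0, got {half_width}")
    mask = grid.mask
    m = mask.astype(float)
    v = np.where(mask, grid.toxicity, 0.0)
    cnt = _window_sums(m, half_width)
    mean = np.divide(_window_sums(v, half_width), cnt, out=np.zeros_like(v), where=cnt > 0)
    # Focal SD is shift-invariant; centring on the masked global mean keeps
    # the sum-of-squares variance form accurate when values share a large
    # common component.
    mu = grid.toxicity[mask].mean() if mask.any() else 0.0
    vc = np.where(mask, grid.toxicity - mu, 0.0)
    s1 = _window_sums(vc, half_width)
    s2 = _window_sums(vc * vc, half_width)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = s2 / cnt - (s1 / cnt) ** 2
    sd = np.sqrt(np.clip(var, 0.0, None))
    sd[~mask] = np.nan
    mean[~mask] = np.nan
    return cnt, mean, sd


def focal_sd(grid: ContextGrid, half_width: int) -> np.ndarray:
    """Population SD over the square focal window centred on each pixel.

    The window is ``(2 * half_width + 1)`` pixels on a side, includes the
    centre, truncates at grid edges and masked cells, and yields 0 for
    single-member windows.  Masked pixels are NaN.
    """
    _, _, sd = _focal_moments(grid, half_width)
    return sd


def focal_mean(grid: ContextGrid, half_width: int) -> np.ndarray:
    """Mean over the truncated square focal window at each pixel (NaN where masked)."""
    _, mean, _ = _focal_moments(grid, half_width)
    return mean


def _ratio_surface(
    spec: GridSpec, metric: str, numerator: np.ndarray, denominator: np.ndarray,
    mask: np.ndarray,
) -> MetricSurface:
    undefined = mask & (denominator == 0)
    ok = mask & ~undefined
    values = np.full(spec.shape, np.nan)
    values[ok] = numerator[ok] / denominator[ok]
    return MetricSurface(
        spec=spec, metric=metric, values=values, undefined=undefined, mask=mask
    )


def pcv_surface(grid: ContextGrid, half_width: int = 1, ddof: int = 0) -> MetricSurface:
    """Positional coefficient of variation.

    ``PCV_i = SD(pixel i and its neighbours) / est_i`` with a 3x3 window by
    default (the pixel and its eight immediate neighbours — 1.5 mi on a
    side at the default 0.5 mi pixel).  Pixels with ``est_i = 0`` are
    undefined.
    """
    if ddof == 0:
        sd = focal_sd(grid, half_width)
    else:
        sd = _focal_sd_ddof(grid, half_width, ddof)
    return _ratio_surface(grid.spec, "PCV", sd, grid.toxicity, grid.mask)


def _focal_sd_ddof(grid: ContextGrid, half_width: int, ddof: int) -> np.ndarray:
    cnt, _, sd = _focal_moments(grid, half_width)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sd * np.sqrt(cnt / np.maximum(cnt - ddof, 0))
    out[np.asarray(cnt <= ddof) & grid.mask] = np.nan
    return out


def ncv_surface(
    grid: ContextGrid, nb: NeighborhoodSpec | None = None, ddof: int = 0
) -> MetricSurface:
    """Neighbourhood-size coefficient of variation.

    For each pixel, the mean toxicity is computed over each of the nested
    square neighbourhoods in ``nb`` (unmasked members only, truncated at
    edges); ``NCV_i`` is the population SD of those means divided by the
    singleton mean ``est_i``.  Pixels with ``est_i = 0`` are undefined.
    """
    if nb is None:
        nb = NeighborhoodSpec()
    means = np.stack([focal_mean(grid, h) for h in nb.half_widths], axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.std(means, axis=0, ddof=ddof)
    return _ratio_surface(grid.spec, "NCV", sd, grid.toxicity, grid.mask)


def lcv_surface(stack: YearStack, ddof: int = 0) -> MetricSurface:
    """Life-course coefficient of variation.

    Per pixel, the population SD of the toxicity score across the stack's
    years divided by the median across years (even counts: mean of the two
    central order statistics).  A zero median makes the pixel undefined.
    Requires at least two years.
    """
    if len(stack) < 2:
        raise ValueError(f"LCV needs >= 2 years, stack has {len(stack)}")
    cube = stack.toxicity_cube()
    sd = np.std(cube, axis=0, ddof=ddof)
    med = np.median(cube, axis=0)
    return _ratio_surface(stack.spec, "LCV", sd, med, stack.mask)


def bin_metric(surface: MetricSurface, scheme: BinScheme | None = None) -> MetricSurface:
    """Classify a metric surface into the shared 6-bin scheme.

    Intervals are left-closed right-open with an unbounded top bin
    (label 6 covers "5 and above" under the default edges).  Undefined and
    masked pixels get bin 0.
    """
    if scheme is None:
        scheme = BinScheme()
    ok = surface.defined_mask
    bins = np.zeros(surface.spec.shape, dtype=int)
    bins[ok] = scheme.assign(surface.values[ok])
    return replace(surface, bin=bins, scheme=scheme)
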