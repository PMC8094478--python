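"""Contact-to-pixel linkage and population/cohort summaries.

Each cohort contact is joined to the pixel its coordinates fall in and to
the context grid for the calendar year of the visit.  Rows that cannot be
linked (outside the grid extent, on a masked-out pixel, or in a year the
stack does not cover) are *flagged with a reason code, never dropped*:
the linkage table always has exactly one row per contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactTable
from .grids import YearStack, points_to_pixels
from .metrics import BinScheme, MetricSurface

__all__ = [
    "LinkageTable",
    "link_contacts",
    "weighted_summary",
    "summarize_toxicity",
    "corr_pop_toxicity",
]

#: linkage reason codes
LINK_OK = "ok"
LINK_OUT_OF_GRID = "out_of_grid"
LINK_YEAR_MISSING = "year_missing"
LINK_MASKED_PIXEL = "masked_pixel"


@dataclass
class LinkageTable:
    """One row per contact, joined to pixel indices and per-year values.

    ``link_status`` is ``"ok"`` or a reason code; ``row``/``col`` are -1
    and value columns NaN on flagged rows.
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ok(self) -> pd.DataFrame:
        return self.df[self.df["link_status"] == LINK_OK]

    @property
    def flagged(self) -> pd.DataFrame:
        return self.df[self.df["link_status"] != LINK_OK]

    def status_counts(self) -> dict[str, int]:
        return self.df["link_status"].value_counts().to_dict()

    def to_csv(self, path: str) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "LinkageTable":
        return cls(pd.read_csv(path))


def link_contacts(
    contacts: ContactTable,
    stack: YearStack,
    surfaces: dict[str, MetricSurface] | None = None,
) -> LinkageTable:
    """Join every contact to its pixel and that year's context values.

    ``surfaces`` optionally maps lower-case metric names (``"pcv"`` etc.)
    to :class:`MetricSurface` objects on the same grid; their per-pixel
    values are attached as extra columns.
    """
    if len(stack) == 0:
        raise ValueError("empty year stack")
    df = contacts.df.copy()
    spec = stack.spec
    rows, cols, inside = points_to_pixels(
        df["x"].to_numpy(), df["y"].to_numpy(), spec
    )
    df["row"] = rows
    df["col"] = cols

    status = np.full(len(df), LINK_OK, dtype=object)
    status[~inside] = LINK_OUT_OF_GRID
    year_ok = df["year"].isin(stack.years).to_numpy()
    status[inside & ~year_ok] = LINK_YEAR_MISSING
    masked = np.zeros(len(df), dtype=bool)
    masked[inside] = ~stack.mask[rows[inside], cols[inside]]
    status[inside & year_ok & masked] = LINK_MASKED_PIXEL

    ok = status == LINK_OK
    tox = np.full(len(df), np.nan)
    for year, idx in df.groupby("year").groups.items():
        idx = np.asarray(idx)
        sel = idx[ok[idx]]
        if len(sel) == 0 or not stack.has_year(int(year)):
            continue
        grid = stack.by_year(int(year))
        tox[sel] = grid.toxicity[rows[sel], cols[sel]]
    df["toxicity"] = tox
    df["link_status"] = status

    if surfaces:
        for name, surf in surfaces.items():
            vals = np.full(len(df), np.nan)
            vals[ok] = surf.values[rows[ok], cols[ok]]
            df[name.lower()] = vals
    df.loc[~pd.Series(ok), ["row", "col"]] = -1
    return LinkageTable(df)


def weighted_summary(
    values: np.ndarray,
    weights: np.ndarray,
    scheme: BinScheme | None = None,
) -> dict:
    """Weighted mean, lower weighted median and binned histogram.

    NaN values are excluded together with their weights and reported under
    ``excluded_n`` / ``excluded_weight``; histogram masses sum to the total
    weight of the defined values.  The weighted median is the smallest
    value whose cumulative weight reaches half the total (no
    interpolation).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError(f"length mismatch: {values.shape} vs {weights.shape}")
    if (weights < 0).any():
        raise ValueError("negative weights")
    defined = np.isfinite(values)
    v, w = values[defined], weights[defined]
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight over defined values is zero")
    mean = float((w * v).sum() / total)
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    median = float(v[order][np.searchsorted(cum, total / 2)])
    if scheme is None:
        scheme = BinScheme()
    labels = scheme.assign(v)
    mass = np.bincount(labels, weights=w, minlength=scheme.n_bins + 1)[1:]
    intervals = scheme.intervals()
    hist = pd.DataFrame(
        {
            "bin": np.arange(1, scheme.n_bins + 1),
            "lower": [lo for lo, _ in intervals],
            "upper": [hi for _, hi in intervals],
            "weight_mass": mass,
        }
    )
    return {
        "mean": mean,
        "median": median,
        "histogram": hist,
        "total_weight": float(total),
        "excluded_n": int((~defined).sum()),
        "excluded_weight": float(weights[~defined].sum()),
    }


def summarize_toxicity(
    grid,
    weighting: str = "context",
    linkage: LinkageTable | None = None,
    per_person: bool = False,
) -> float:
    """log10 of the (weighted) mean toxicity score.

    ``weighting``:

    * ``"context"`` — plain mean over all unmasked pixels;
    * ``"population"`` — pixel scores weighted by resident population
      (requires the grid's population band);
    * ``"cohort"`` — mean over the linked cohort contacts (requires
      ``linkage``); with ``per_person=True`` each person's contacts are
      averaged first so every person counts once.

    The mean is taken *before* the log.  A zero mean returns NaN.
    """
    if weighting == "context":
        mean = float(grid.toxicity[grid.mask].mean())
    elif weighting == "population":
        if grid.population is None:
            raise ValueError("population weighting requires a population raster")
        pop = grid.population[grid.mask]
        tox = grid.toxicity[grid.mask]
        if pop.sum() <= 0:
            raise ValueError("total population is zero")
        mean = float((pop * tox).sum() / pop.sum())
    elif weighting == "cohort":
        if linkage is None:
            raise ValueError("cohort weighting requires a LinkageTable")
        ok = linkage.ok
        if len(ok) == 0:
            raise ValueError("no linked contacts")
        if per_person:
            mean = float(ok.groupby("person_id")["toxicity"].mean().mean())
        else:
            mean = float(ok["toxicity"].mean())
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if mean <= 0:
        return float("nan")
    return float(np.log10(mean))


def corr_pop_toxicity(grid, offset: float = 1.0) -> float:
    """Pearson correlation of population with log10(toxicity + offset).

    Computed across unmasked pixels.  Scores of zero occur, so the log
    needs an offset; the default is +1.  Returns NaN if either vector is
    constant; fewer than 3 unmasked pixels is an error.
    """
    if grid.population is None:
        raise ValueError("corr_pop_toxicity requires a population raster")
    m = grid.mask
    if m.sum() < 3:
        raise ValueError(f"need >= 3 unmasked pixels, have {int(m.sum())}")
    pop = grid.population[m]
    logtox = np.log10(grid.toxicity[m] + offset)
    if np.ptp(pop) == 0 or np.ptp(logtox) == 0:
        return float("nan")
    r, _ = stats.pearsonr(pop, logtox)
    return float(r)
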