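"""Temporal analyses over persons: moves, exposure transitions, day/night.

Exposure context can change through two channels: the context shifts
around a stationary household (channel 1), or the household moves
(channel 2).  Stayer transitions isolate channel 1; mover transitions mix
both.  The day/night comparison contrasts the same child's residence and
day-care exposure within a wave.

Correlations default to the log10(x + 1) scale: toxicity scores are
heavy-tailed and a raw-scale Pearson r is dominated by single extreme
events.  Pass ``transform="identity"`` for the raw scale.  Reported r is
the plain pooled Pearson correlation — within-person dependence is not
adjusted for.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .grids import YearStack
from .linkage import LINK_OK, LinkageTable

__all__ = [
    "classify_moves",
    "build_transitions",
    "build_day_night",
    "corr_by_group",
]


def _residence_frame(linkage: LinkageTable | pd.DataFrame) -> pd.DataFrame:
    df = linkage.df if isinstance(linkage, LinkageTable) else linkage
    return df[df["location_type"] == "residence"].copy()


def classify_moves(
    linkage: LinkageTable | pd.DataFrame, tolerance: float = 0.0
) -> pd.DataFrame:
    """Flag residential moves between consecutive observed waves.

    A move is a Euclidean displacement of the residence coordinate greater
    than ``tolerance`` (default 0: any coordinate change counts; set e.g.
    0.1 km to absorb GPS jitter).  One output row per person per
    consecutive wave pair, with the displacement and the ``moved`` flag.
    Waves with non-finite coordinates are skipped; the count is in the
    result's ``attrs["skipped_endpoints"]``.
    """
    res = _residence_frame(linkage)
    res = res.sort_values(["person_id", "wave"], kind="stable")
    finite = np.isfinite(res["x"].to_numpy()) & np.isfinite(res["y"].to_numpy())
    skipped = int((~finite).sum())
    res = res[finite]
    g = res.groupby("person_id", sort=False)
    prev = g[["wave", "year", "x", "y"]].shift(1)
    have_prev = prev["wave"].notna()
    dist = np.hypot(res["x"] - prev["x"], res["y"] - prev["y"])
    out = pd.DataFrame(
        {
            "person_id": res["person_id"],
            "wave_from": prev["wave"],
            "wave_to": res["wave"],
            "year_from": prev["year"],
            "year_to": res["year"],
            "distance": dist,
            "moved": dist > tolerance,
        }
    )[have_prev].reset_index(drop=True)
    out.attrs["skipped_endpoints"] = skipped
    return out


def build_transitions(
    linkage: LinkageTable,
    stack: YearStack,
    tolerance: float = 0.0,
    max_gap: int | None = None,
) -> pd.DataFrame:
    """Year-over-year exposure pairs per person, split by moved/stayed.

    For each person and consecutive pair of observed residence years,
    ``exposure_from`` is the toxicity of the year-t−1 grid at the t−1
    residence pixel and ``exposure_to`` the year-t grid at the year-t
    residence pixel — so stayers see pure context change and movers see
    context change plus relocation.  Where a person has several residence
    contacts in one year the latest wave represents that year.

    Pairs whose endpoints could not be linked are skipped; counts by
    reason are in ``attrs["skipped"]``.  ``gap`` marks pairs more than one
    calendar year apart (dropped entirely if ``max_gap`` is given and
    exceeded).
    """
    res = _residence_frame(linkage)
    res = res.sort_values(["person_id", "year", "wave"], kind="stable")
    res = res.groupby(["person_id", "year"], sort=False).tail(1)

    skipped = {"endpoint_not_linked": 0, "gap_exceeded": 0}
    rows = []
    for pid, sub in res.groupby("person_id", sort=False):
        sub = sub.sort_values("year")
        recs = sub.to_dict("records")
        for a, b in zip(recs, recs[1:]):
            if a["link_status"] != LINK_OK or b["link_status"] != LINK_OK:
                skipped["endpoint_not_linked"] += 1
                continue
            gap = int(b["year"] - a["year"]) > 1
            if max_gap is not None and b["year"] - a["year"] > max_gap:
                skipped["gap_exceeded"] += 1
                continue
            dist = float(np.hypot(b["x"] - a["x"], b["y"] - a["y"]))
            rows.append(
                {
                    "person_id": pid,
                    "year_from": int(a["year"]),
                    "year_to": int(b["year"]),
                    "exposure_from": float(a["toxicity"]),
                    "exposure_to": float(b["toxicity"]),
                    "distance": dist,
                    "moved": dist > tolerance,
                    "gap": gap,
                    "state": a.get("state"),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "year_from",
            "year_to",
            "exposure_from",
            "exposure_to",
            "distance",
            "moved",
            "gap",
            "state",
        ],
    )
    out.attrs["skipped"] = skipped
    return out


def build_day_night(linkage: LinkageTable) -> pd.DataFrame:
    """Contemporaneous residence / day-care exposure pairs per person-wave.

    Only waves where both location types linked successfully contribute;
    both exposures come from the same year's grid by construction.
    """
    ok = linkage.ok
    res = ok[ok["location_type"] == "residence"]
    dc = ok[ok["location_type"] == "daycare"]
    merged = res.merge(
        dc,
        on=["person_id", "wave", "year"],
        suffixes=("_res", "_dc"),
    )
    out = pd.DataFrame(
        {
            "person_id": merged["person_id"],
            "wave": merged["wave"],
            "year": merged["year"],
            "exposure_residence": merged["toxicity_res"],
            "exposure_daycare": merged["toxicity_dc"],
            "state": merged["state_res"],
        }
    )
    return out.reset_index(drop=True)


_TRANSFORMS = {
    "log10p1": lambda x: np.log10(np.asarray(x, dtype=float) + 1.0),
    "identity": lambda x: np.asarray(x, dtype=float),
}


def corr_by_group(
    records: pd.DataFrame,
    x_col: str,
    y_col: str,
    by: list[str] | None = None,
    transform: str = "log10p1",
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of two exposure columns, per group and pooled.

    ``by`` lists grouping columns (e.g. ``["state", "moved"]`` for the
    mover/stayer contrast, ``["state"]`` for day/night).  The pooled row
    has ``"all"`` in every grouping column.  Groups with fewer than
    ``min_n`` records or a constant vector get ``r = NaN``.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    f = _TRANSFORMS[transform]

    def one(sub: pd.DataFrame) -> float:
        x, y = f(sub[x_col]), f(sub[y_col])
        if len(sub) < min_n or np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan")
        return float(stats.pearsonr(x, y)[0])

    rows = []
    if by:
        for key, sub in records.groupby(by, sort=True, dropna=False):
            key = key if isinstance(key, tuple) else (key,)
            rows.append(dict(zip(by, key)) | {"n": len(sub), "r": one(sub)})
    pooled = {c: "all" for c in (by or [])}
    rows.append(pooled | {"n": len(records), "r": one(records)})
    out = pd.DataFrame(rows)
    out["transform"] = transform
    return out
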