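"""Result bundles: weighted histograms, summary stats and correlation tables.

Mirrors the shape of the study outputs: per-metric population-weighted
histograms for the statewide population next to contact-weighted cohort
histograms, log-mean toxicity summaries, and the mover/stayer and
day/night correlation tables.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .linkage import LinkageTable, weighted_summary
from .metrics import BinScheme, MetricSurface
from .mobility import corr_by_group

__all__ = ["metric_histograms", "correlation_report", "write_report"]


def metric_histograms(
    surfaces: dict[str, MetricSurface],
    population: np.ndarray | None = None,
    linkage: LinkageTable | None = None,
    scheme: BinScheme | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram and mean/median tables per metric and weighting.

    For each surface: a population-weighted histogram over defined pixels
    (if ``population`` given) and a contact-weighted cohort histogram over
    the linked metric column (if ``linkage`` given and carries the
    column).  Returns ``(histograms, summaries)``.
    """
    scheme = scheme or BinScheme()
    hist_rows, summ_rows = [], []

    def add(metric: str, weighting: str, values, weights) -> None:
        s = weighted_summary(values, weights, scheme)
        h = s["histogram"].copy()
        h.insert(0, "metric", metric)
        h.insert(1, "weighting", weighting)
        hist_rows.append(h)
        summ_rows.append(
            {"metric": metric, "weighting": weighting, "mean": s["mean"],
             "median": s["median"], "total_weight": s["total_weight"],
             "excluded_n": s["excluded_n"],
             "excluded_weight": s["excluded_weight"]}
        )

    for name, surf in surfaces.items():
        key = name.lower()
        inside = surf.mask
        if population is not None:
            vals = np.where(surf.defined_mask, surf.values, np.nan)[inside]
            add(key, "population", vals, population[inside])
        if linkage is not None and key in linkage.df.columns:
            ok = linkage.ok
            add(key, "cohort", ok[key].to_numpy(), np.ones(len(ok)))
    hist = (
        pd.concat(hist_rows, ignore_index=True)
        if hist_rows
        else pd.DataFrame(columns=["metric", "weighting", "bin", "lower", "upper",
                                   "weight_mass"])
    )
    return hist, pd.DataFrame(summ_rows)


def correlation_report(
    transitions: pd.DataFrame | None = None,
    day_night: pd.DataFrame | None = None,
    transform: str = "log10p1",
) -> pd.DataFrame:
    """Stacked correlation table: mover/stayer by state, plus day/night."""
    parts = []
    if transitions is not None and len(transitions):
        t = corr_by_group(
            transitions, "exposure_from", "exposure_to",
            by=["state", "moved"], transform=transform,
        )
        t.insert(0, "analysis", "life_course")
        parts.append(t)
    if day_night is not None and len(day_night):
        d = corr_by_group(
            day_night, "exposure_residence", "exposure_daycare",
            by=["state"], transform=transform,
        )
        d.insert(0, "analysis", "day_night")
        d["moved"] = pd.NA
        parts.append(d)
    if not parts:
        raise ValueError("no transitions or day/night records to report on")
    return pd.concat(parts, ignore_index=True)


def write_report(
    outdir: str,
    surfaces: dict[str, MetricSurface] | None = None,
    population: np.ndarray | None = None,
    linkage: LinkageTable | None = None,
    transitions: pd.DataFrame | None = None,
    day_night: pd.DataFrame | None = None,
    scheme: BinScheme | None = None,
) -> dict[str, str]:
    """Write the CSV report bundle; returns {name: path} of files written."""
    os.makedirs(outdir, exist_ok=True)
    written: dict[str, str] = {}
    if surfaces:
        hist, summ = metric_histograms(surfaces, population, linkage, scheme)
        hist_path = os.path.join(outdir, "histograms.csv")
        summ_path = os.path.join(outdir, "summaries.csv")
        hist.to_csv(hist_path, index=False)
        summ.to_csv(summ_path, index=False)
        written["histograms"] = hist_path
        written["summaries"] = summ_path
    if transitions is not None or day_night is not None:
        corr = correlation_report(transitions, day_night)
        corr_path = os.path.join(outdir, "correlations.csv")
        corr.to_csv(corr_path, index=False)
        written["correlations"] = corr_path
    return written
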