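"""Independent brute-force oracles the fast implementations are checked against.

Everything here loops over pixels and window members directly and uses
numpy's two-pass std/median on the gathered members — no shared code with
the package's focal-statistics path.
"""

from __future__ import annotations

import math

import numpy as np


def window_members(values, mask, r, c, half_width):
    """Unmasked values in the truncated square window centred on (r, c)."""
    n_rows, n_cols = values.shape
    out = []
    for rr in range(max(0, r - half_width), min(n_rows, r + half_width + 1)):
        for cc in range(max(0, c - half_width), min(n_cols, c + half_width + 1)):
            if mask[rr, cc]:
                out.append(values[rr, cc])
    return np.array(out)


def naive_focal_sd(grid, half_width, ddof=0):
    out = np.full(grid.shape, np.nan)
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            if not grid.mask[r, c]:
                continue
            members = window_members(grid.toxicity, grid.mask, r, c, half_width)
            out[r, c] = np.std(members, ddof=ddof) if len(members) > ddof else np.nan
    return out


def naive_pcv(grid, half_width=1):
    """(values, undefined) of the positional CV, triple-loop."""
    sd = naive_focal_sd(grid, half_width)
    values = np.full(grid.shape, np.nan)
    undefined = np.zeros(grid.shape, dtype=bool)
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            if not grid.mask[r, c]:
                continue
            est = grid.toxicity[r, c]
            if est == 0:
                undefined[r, c] = True
            else:
                values[r, c] = sd[r, c] / est
    return values, undefined


def naive_ncv(grid, half_widths=(0, 1, 2, 3, 4, 9)):
    values = np.full(grid.shape, np.nan)
    undefined = np.zeros(grid.shape, dtype=bool)
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            if not grid.mask[r, c]:
                continue
            means = [
                np.mean(window_members(grid.toxicity, grid.mask, r, c, h))
                for h in half_widths
            ]
            est = grid.toxicity[r, c]
            if est == 0:
                undefined[r, c] = True
            else:
                values[r, c] = np.std(means) / est
    return values, undefined


def naive_lcv(stack):
    shape = stack.spec.shape
    values = np.full(shape, np.nan)
    undefined = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            if not stack.mask[r, c]:
                continue
            series = np.array([g.toxicity[r, c] for g in stack])
            med = np.median(series)
            if med == 0:
                undefined[r, c] = True
            else:
                values[r, c] = np.std(series) / med
    return values, undefined


def floor_point_to_pixel(x, y, spec):
    """Independent floor-based cell assignment with the same conventions."""
    col = math.floor((x - spec.origin_x) / spec.pixel_size)
    row = math.floor((spec.origin_y - y) / spec.pixel_size)
    if 0 <= row < spec.n_rows and 0 <= col < spec.n_cols:
        return (row, col)
    return (-1, -1)


def expanded_summary(values, weights):
    """Unweighted mean/median of the integer-weight-expanded vector."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights)
    expanded = np.repeat(values, weights.astype(int))
    order = np.sort(expanded)
    # lower median: smallest element at cumulative count >= half
    k = int(np.ceil(len(order) / 2)) - 1
    return float(expanded.mean()), float(order[k])
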