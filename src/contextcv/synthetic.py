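"""Synthetic RSEI-like study generator: surfaces, population, cohort.

Emulates the *structural signature* of a screening-model toxicity surface
— point releases with rapid exponential distance decay cut off hard at a
maximum effect radius (30 mi), heavy-tailed release magnitudes, multi-year
persistence with occasional acute single-year events — plus a population
raster with urban kernels over a sparse rural background, and a cohort of
households observed at residence and day-care locations over several
waves, with residential moves.  No plume physics, chemistry or census
allocation is modelled: the uncertainty metrics respond to the
decay-plus-cutoff geometry, not to the physics behind it.

Everything is deterministic given the master seed; each component draws
from its own stream spawned from that seed, so components can be
regenerated independently yet reproducibly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .contacts import ContactTable
from .grids import (
    OUT_OF_GRID, ContextGrid, GridSpec, YearStack, pixel_centers, point_to_pixel,
)

__all__ = [
    "ScenarioConfig",
    "SimulatedStudy",
    "simulate_surface",
    "simulate_population",
    "simulate_cohort",
    "simulate_study",
]

MILE_KM = 1.609344


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of the synthetic study, with desk-scale defaults.

    Lengths are kilometres.  The defaults describe a ~60 x 60 mile region
    on a half-mile grid over six years, a couple of dozen release sites
    with log-normal (heavy-tailed) magnitudes decaying over ~2 miles and
    cut off at 30 miles, ~7% zero-population pixels, and 150 households
    visited at eight waves (months 2–60) at both residence and day care.
    """

    # grid
    n_rows: int = 120
    n_cols: int = 120
    pixel_size: float = 0.805
    years: tuple[int, ...] = (2003, 2004, 2005, 2006, 2007, 2008)
    # release sites
    n_sites: int = 25
    magnitude_mu: float = 2.0
    magnitude_sigma: float = 2.0
    decay_length: float = 2 * MILE_KM
    cutoff_radius: float = 30 * MILE_KM
    persistence: float = 0.9
    shock_sd: float = 0.3
    acute_rate: float = 0.05
    acute_multiplier: float = 50.0
    # extra release deposited in the site's own pixel: the release pixel is
    # far hotter than even its nearest neighbours (the near-field spike that
    # shows as hollow boxes in neighbourhood-CV maps)
    near_field_boost: float = 10.0
    # population
    n_centers: int = 3
    center_mass: float = 2000.0
    center_sd_pixels: float = 5.0
    rural_rate: float = 3.0
    zero_pop_fraction: float = 0.07
    # industry-near-towns coupling: probability a release site sits near an
    # urban centre (drives the weak positive population-toxicity correlation)
    p_site_near_center: float = 0.25
    site_center_sd_pixels: float = 15.0
    # cohort
    n_households: int = 150
    wave_months: tuple[int, ...] = (2, 6, 15, 24, 35, 48, 58, 60)
    p_move: float = 0.1
    daycare_radius: float = 8.0
    p_daycare_same: float = 0.3
    study_region_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("persistence", "acute_rate", "p_move", "p_daycare_same",
                     "zero_pop_fraction", "p_site_near_center"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("pixel_size", "decay_length", "cutoff_radius",
                     "acute_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.near_field_boost < 0:
            raise ValueError("near_field_boost must be >= 0")
        if len(self.years) < 1:
            raise ValueError("need at least one year")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if not 0 < self.study_region_fraction <= 1:
            raise ValueError("study_region_fraction must be in (0, 1]")

    @property
    def grid_spec(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows, n_cols=self.n_cols, pixel_size=self.pixel_size,
            origin_x=0.0, origin_y=self.n_rows * self.pixel_size,
        )

    def study_region(self) -> tuple[int, int, int, int]:
        """Central (row0, row1, col0, col1) half-open pixel box for the cohort."""
        fr = self.study_region_fraction
        r0 = int(self.n_rows * (1 - fr) / 2)
        c0 = int(self.n_cols * (1 - fr) / 2)
        r1 = max(r0 + 1, r0 + int(self.n_rows * fr))
        c1 = max(c0 + 1, c0 + int(self.n_cols * fr))
        return r0, r1, c0, c1

    def to_dict(self) -> dict:
        return asdict(self)


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def draw_urban_centers(
    config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Urban centre coordinates, shape (n_centers, 2)."""
    spec = config.grid_spec
    cx = rng.uniform(spec.origin_x, spec.x_max, config.n_centers)
    cy = rng.uniform(spec.y_min, spec.origin_y, config.n_centers)
    return np.column_stack([cx, cy])


def simulate_surface(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    centers: np.ndarray | None = None,
) -> tuple[YearStack, pd.DataFrame]:
    """Multi-year toxicity surfaces from decaying point releases.

    Pixel score at year t is the sum over active sites of
    ``m_k(t) * exp(-d/lambda)`` for pixel-centre-to-site distance
    ``d <= R``, and exactly 0 beyond the cutoff — the hard edge that shows
    up as rings in the derived uncertainty surfaces.  Site magnitudes
    follow a geometric random walk (``exp`` of Gaussian shocks), die for
    good with probability ``1 - persistence`` each year, and suffer acute
    single-year multiplications at ``acute_rate``.

    If ``centers`` (urban centre coordinates) are supplied, each site is
    placed near a random centre with probability ``p_site_near_center``
    (Gaussian scatter, ``site_center_sd_pixels``), emulating industry
    siting near towns — the source of the weak positive
    population-toxicity correlation; otherwise sites are uniform over the
    grid.

    Returns the stack and a site table (position, per-year effective
    magnitude) for diagnostics.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spec = config.grid_spec
    X, Y = pixel_centers(spec)

    sx = rng.uniform(spec.origin_x, spec.x_max, config.n_sites)
    sy = rng.uniform(spec.y_min, spec.origin_y, config.n_sites)
    if centers is not None and len(centers) and config.p_site_near_center > 0:
        near = rng.random(config.n_sites) < config.p_site_near_center
        which = rng.integers(0, len(centers), config.n_sites)
        sd = config.site_center_sd_pixels * config.pixel_size
        jitter = rng.normal(0.0, sd, (config.n_sites, 2))
        sx = np.where(near, centers[which, 0] + jitter[:, 0], sx)
        sy = np.where(near, centers[which, 1] + jitter[:, 1], sy)
        sx = np.clip(sx, spec.origin_x, spec.x_max)
        sy = np.clip(sy, spec.y_min, spec.origin_y)
    m = rng.lognormal(config.magnitude_mu, config.magnitude_sigma, config.n_sites)
    active = np.ones(config.n_sites, dtype=bool)

    decay_fields = []
    for k in range(config.n_sites):
        d = np.hypot(X - sx[k], Y - sy[k])
        f = np.where(d <= config.cutoff_radius, np.exp(-d / config.decay_length), 0.0)
        if config.near_field_boost > 0:
            rc = point_to_pixel(sx[k], sy[k], spec)
            if rc != OUT_OF_GRID:
                f[rc] += config.near_field_boost
        decay_fields.append(f)

    grids, site_rows = [], []
    for t, year in enumerate(config.years):
        acute = rng.random(config.n_sites) < config.acute_rate
        eff = m * np.where(acute, config.acute_multiplier, 1.0) * active
        tox = np.zeros(spec.shape)
        for k in range(config.n_sites):
            if eff[k] > 0:
                tox += eff[k] * decay_fields[k]
        grids.append(ContextGrid(spec=spec, toxicity=tox, year=year))
        for k in range(config.n_sites):
            site_rows.append(
                {"site": k, "x": sx[k], "y": sy[k], "year": year,
                 "magnitude": eff[k], "active": bool(active[k]),
                 "acute": bool(acute[k] and active[k])}
            )
        # evolve for next year
        m = m * np.exp(rng.normal(0.0, config.shock_sd, config.n_sites))
        active &= rng.random(config.n_sites) < config.persistence
    return YearStack(grids), pd.DataFrame(site_rows)


def simulate_population(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    centers: np.ndarray | None = None,
) -> np.ndarray:
    """Population raster: Gaussian urban kernels over Poisson rural noise.

    The rural background is then thinned (random pixels zeroed) to bring
    the zero-population pixel fraction up to the configured target; if the
    raster already has more zeros than target + 2 percentage points the
    target is unreachable by thinning and an error reports the achieved
    fraction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spec = config.grid_spec
    X, Y = pixel_centers(spec)
    pop = rng.poisson(config.rural_rate, spec.shape).astype(float)
    if centers is None:
        centers = draw_urban_centers(config, rng)
    sd = config.center_sd_pixels * config.pixel_size
    for cx, cy in centers:
        d2 = (X - cx) ** 2 + (Y - cy) ** 2
        kernel = config.center_mass * np.exp(-d2 / (2 * sd**2))
        kernel[d2 > (4 * sd) ** 2] = 0.0  # finite urban footprint
        pop += kernel
    n_pix = pop.size
    zero_now = float((pop == 0).sum()) / n_pix
    target = config.zero_pop_fraction
    if zero_now > target + 0.02:
        raise ValueError(
            f"zero-population target {target:.3f} unreachable by thinning: "
            f"raster already has {zero_now:.3f} zeros "
            f"(rural_rate={config.rural_rate}, n_centers={config.n_centers})"
        )
    n_needed = int(round(max(0.0, target - zero_now) * n_pix))
    if n_needed > 0:
        flat = pop.ravel()
        positive = np.flatnonzero(flat > 0)
        kill = rng.choice(positive, size=n_needed, replace=False)
        flat[kill] = 0.0
        pop = flat.reshape(spec.shape)
    return pop


def _weighted_pixel_choice(
    rng: np.random.Generator, rows: np.ndarray, cols: np.ndarray, weights: np.ndarray,
    size: int | None = None,
):
    p = weights / weights.sum()
    idx = rng.choice(len(rows), size=size, p=p)
    return rows[idx], cols[idx]


def _point_in_pixel(rng, spec: GridSpec, row: int, col: int) -> tuple[float, float]:
    x = spec.origin_x + (col + rng.random()) * spec.pixel_size
    y = spec.origin_y - (row + rng.random()) * spec.pixel_size
    return float(x), float(y)


def simulate_cohort(
    config: ScenarioConfig,
    population: np.ndarray,
    stack: YearStack,
    rng: np.random.Generator | None = None,
) -> tuple[ContactTable, pd.DataFrame]:
    """Cohort of households with residence moves and nearby day care.

    Households are placed population-proportionally inside the central
    study region, split into a western ("NC") and eastern ("PA") stratum
    at the region's middle column.  At each wave after the first the
    residence moves with probability ``p_move`` to a population-weighted
    pixel (fresh uniform point inside it); day care sits in the home pixel
    with probability ``p_daycare_same`` and otherwise in a
    population-weighted pixel whose centre lies within ``daycare_radius``
    of home, re-drawn whenever the residence changes.  Each wave emits one
    residence and one day-care contact.

    Returns the contact table and the ground-truth move log (one row per
    consecutive wave pair per household, with the true ``moved`` flag).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spec = stack.spec
    r0, r1, c0, c1 = config.study_region()
    rr, cc = np.mgrid[r0:r1, c0:c1]
    rr, cc = rr.ravel(), cc.ravel()
    w = population[rr, cc].astype(float)
    if w.sum() <= 0:
        raise ValueError("study region has zero total population")
    mid_col = (c0 + c1) / 2

    base_year = config.years[0]
    wave_years = [base_year + mth // 12 for mth in config.wave_months]

    contact_rows, move_rows = [], []
    for h in range(config.n_households):
        pid = f"h{h:04d}"
        hr, hc = _weighted_pixel_choice(rng, rr, cc, w)
        hx, hy = _point_in_pixel(rng, spec, hr, hc)
        state = "NC" if hc < mid_col else "PA"
        dx, dy = _draw_daycare(rng, config, spec, population, rr, cc, w, hr, hc, hx, hy)
        for wv, (mth, year) in enumerate(zip(config.wave_months, wave_years), start=1):
            if wv > 1:
                moved = bool(rng.random() < config.p_move)
                if moved:
                    px, py = hx, hy
                    hr, hc = _weighted_pixel_choice(rng, rr, cc, w)
                    hx, hy = _point_in_pixel(rng, spec, hr, hc)
                    dx, dy = _draw_daycare(
                        rng, config, spec, population, rr, cc, w, hr, hc, hx, hy
                    )
                    dist = float(np.hypot(hx - px, hy - py))
                else:
                    dist = 0.0
                move_rows.append(
                    {"person_id": pid, "wave_from": wv - 1, "wave_to": wv,
                     "moved": moved, "distance": dist}
                )
            for loc, (x, y) in (("residence", (hx, hy)), ("daycare", (dx, dy))):
                contact_rows.append(
                    {"person_id": pid, "wave": wv, "month": mth, "year": year,
                     "location_type": loc, "x": x, "y": y, "state": state}
                )
    contacts = ContactTable(pd.DataFrame(contact_rows))
    return contacts, pd.DataFrame(move_rows)


def _draw_daycare(rng, config, spec, population, rr, cc, w, hr, hc, hx, hy):
    """Day-care point: home pixel with p_daycare_same, else a nearby pixel."""
    if rng.random() < config.p_daycare_same:
        return hx, hy
    X = spec.origin_x + (cc + 0.5) * spec.pixel_size
    Y = spec.origin_y - (rr + 0.5) * spec.pixel_size
    hcx = spec.origin_x + (hc + 0.5) * spec.pixel_size
    hcy = spec.origin_y - (hr + 0.5) * spec.pixel_size
    near = np.hypot(X - hcx, Y - hcy) <= config.daycare_radius
    near &= w > 0
    if not near.any():
        return hx, hy
    dr, dc = _weighted_pixel_choice(rng, rr[near], cc[near], w[near])
    return _point_in_pixel(rng, spec, dr, dc)


@dataclass
class SimulatedStudy:
    """Bundle of one synthetic study: context stack, population, cohort, truth."""

    config: ScenarioConfig
    stack: YearStack
    population: np.ndarray
    contacts: ContactTable
    truth_moves: pd.DataFrame
    sites: pd.DataFrame

    @property
    def population_grid(self) -> ContextGrid:
        """First-year grid with the population band attached (for summaries)."""
        g = self.stack[0]
        return ContextGrid(
            spec=g.spec, toxicity=g.toxicity, year=g.year,
            population=self.population, mask=g.mask,
        )


def simulate_study(config: ScenarioConfig) -> SimulatedStudy:
    """Compose surface, population and cohort simulators from one master seed.

    Each component draws from its own spawned stream, so two calls with
    equal seeds are bit-identical and components can be regenerated
    independently.
    """
    rng_centers, rng_surface, rng_pop, rng_cohort = _rng_streams(config.seed, 4)
    centers = draw_urban_centers(config, rng_centers)
    stack, sites = simulate_surface(config, rng_surface, centers=centers)
    population = simulate_population(config, rng_pop, centers=centers)
    contacts, truth_moves = simulate_cohort(config, population, stack, rng_cohort)
    # attach the population band to every year's grid
    grids = [
        ContextGrid(spec=g.spec, toxicity=g.toxicity, year=g.year,
                    population=population, mask=g.mask)
        for g in stack
    ]
    return SimulatedStudy(
        config=config, stack=YearStack(grids), population=population,
        contacts=contacts, truth_moves=truth_moves, sites=sites,
    )
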