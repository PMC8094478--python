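# Methods

## Problem setting

`contextcv` addresses a linkage design common in environmental
epidemiology: cohort members are points (projected x/y at each visit),
context is a regular square raster of modelled annual toxicity scores
(with an accompanying population raster), and the join assigns each
contact the value of the pixel it falls in for the year of the visit.
The package quantifies how sensitive that assignment is to four sources
of spatio-temporal uncertainty — positional accuracy, neighbourhood-size
choice, year-of-snapshot, and day versus night location — as per-pixel
descriptive statistics and cohort-level correlations.

## Grid model and conventions

Grids are planar and regular: 0-based (row, col), row 0 northernmost,
origin at the outer north-west corner of pixel (0, 0), square pixels
(default 0.805 km = 0.5 mi). Cell membership is half-open — a point on a
shared vertical edge belongs to the east cell, on a shared horizontal
edge to the south cell — so every point maps to exactly one pixel and the
assignment is testable against a plain floor() oracle. Points outside the
extent are flagged, never clamped. Coordinates are assumed projected;
CRS handling is metadata the package passes through, never computes on.

Nodata cells in input rasters become mask=False pixels. Masked pixels are
excluded from every statistic — focal windows truncate over available
members (they are never zero-filled or NaN-poisoned), which keeps
study-region boundaries from contaminating the metrics.

## The three CV statistics

* `PCV_i = SD_i^neighbourhood / est_i`, default window 3×3 (the pixel and
  its eight immediate neighbours, 1.5 mi on a side at the default pixel
  size — matched to GPS/geocoding-scale positional error).
* `NCV_i = SD(mean over each nested neighbourhood) / est_i` with nested
  square neighbourhoods of 1, 9, 25, 49, 81 and 361 pixels (half-widths
  0, 1, 2, 3, 4, 9). The denominator is the singleton-neighbourhood mean,
  i.e. est_i itself.
* `LCV_i = SD(est_i1 … est_in) / median(est_i1 … est_in)` across the
  years of a stack (n ≥ 2; even n uses the mean of the two central order
  statistics).

All SDs are population SDs (ddof 0): the statistics are descriptive, and
this keeps one- and two-member windows well defined. Every surface
function accepts `ddof=1` for sample SDs. Windows include the centre
pixel.

Zero-denominator pixels are *undefined* — a first-class state, not an
error and not zero. Undefined propagates: no bin label (bin 0), excluded
from weighted summaries with its weight reported, written as nodata in
rasters.

Numerics: focal counts/sums/sums-of-squares are computed by correlation
with a ones kernel (zero-padded, with explicit member counts, so padding
never leaks into a statistic). Values are centred on the masked global
mean before the sum-of-squares variance form — focal SD is
shift-invariant, so this is exact, and it suppresses cancellation when
values share a large common component. The suite verifies agreement with
a brute-force two-pass loop to 1e-12 relative tolerance on random masked
grids. The metrics are scale-invariant (c·grid gives the same surface)
but deliberately not shift-invariant — adding a constant moves the
denominator and not the SD — and the suite pins both facts.

## Binning

One shared six-bin classification keeps surfaces comparable across
metrics: left-closed right-open intervals with default edges 0.025, 0.05,
0.075, 0.5, 5.0, the top bin unbounded ("5 and above"). The third edge is
0.075, continuing the 0.025-wide low bins; the fourth and fifth edges
(0.5, 5.0) separate moderate from high and very high uncertainty. The
whole edge vector is configurable.

## Linkage and summaries

`link_contacts` preserves row count exactly: every contact is linked or
flagged (`out_of_grid`, `year_missing`, `masked_pixel`), and the CLI
asserts input = linked + flagged at every stage. Weighted summaries use
the lower weighted median (smallest value whose cumulative weight reaches
half the total — deterministic, no interpolation) and conserve histogram
mass: bin masses plus excluded-undefined mass equal total weight exactly.
Toxicity level summaries report log10 of the weighted mean (mean before
log; zero mean is undefined); weightings are context (all pixels),
population (pixel population), and cohort (each contact once —
a person observed at 8 waves contributes 8 rows, matching the linkage
unit; a per-person collapse is available via `per_person=True`).
The population–toxicity correlation is Pearson r between pixel population
and log10(toxicity + 1); scores of zero occur so an offset is mandatory,
and +1 is the configurable default.

## Mobility and day/night

Moves are coordinate displacements beyond a tolerance (default 0; set
~0.1 km to absorb GPS jitter). Transitions pair consecutive observed
residence years per person: exposure_from is the year-(t−1) grid at the
year-(t−1) residence, exposure_to the year-t grid at the year-t
residence — stayers therefore isolate in-place context change, movers add
relocation. Gaps over one calendar year are flagged. Correlations default
to log10(x+1): scores are heavy-tailed and raw-scale Pearson r is
dominated by single extreme events (`transform="identity"` gives raw).
Reported r is the plain pooled Pearson correlation; within-person
dependence across multiple transitions is not adjusted for.

## Synthetic study generator

The generator emulates the structural signature of a screening-model
toxicity surface, not its physics. Pixel score = Σ over active sites of
m_k(t)·exp(−d/λ) for centre-to-site distance d ≤ R, exactly zero beyond
the hard cutoff R. Defaults, chosen as a realistic desk-scale scenario:

| parameter | default | why |
|---|---|---|
| grid | 120×120 px of 0.805 km | ~60×60 mi region at half-mile resolution |
| years | 2003–2008 | six annual surfaces spanning the cohort's waves |
| sites | 25, log-normal m with μ=2, σ=2 | heavy-tailed release magnitudes (max/median positive pixel > 10²) |
| decay length λ | 2 mi | "rapid, roughly exponential" decay; free parameter, exposed in config |
| cutoff R | 30 mi (48.280 km) | the screening model's maximum effect radius; source of ring artifacts |
| near-field boost | +10·m in the release pixel | the release pixel is far hotter than even its nearest neighbours (hollow-box signature in NCV maps) |
| persistence ρ | 0.9/yr, shock SD 0.3 | multi-year persistence with drift |
| acute events | rate 0.05, ×50 | single-year spikes |
| population | 3 Gaussian urban centres + Poisson(3) rural, 7% zero-population pixels | rural states with towns |
| site–centre coupling | p=0.25, scatter 15 px | industry near towns ⇒ weak positive population–toxicity correlation (mean r ≈ 0.12 across seeds) |
| cohort | 150 households, 8 waves at months 2–60, p_move 0.1/wave, day care within 8 km (same pixel w.p. 0.3) | longitudinal birth-cohort structure with residence + day-care contacts |

Households are placed population-proportionally in a central study
region split into a western and an eastern stratum ("NC"/"PA" labels).
The generator returns a ground-truth move log; `classify_moves` at
tolerance 0 must (and does) reproduce it exactly.

All randomness flows from one master seed through independently spawned
per-component streams: equal seeds give bit-identical studies, and
components can be regenerated separately.

What the generator does **not** emulate: plume physics (stack heights,
wind, topography), chemistry-specific toxicity weighting, census-based
population allocation, per-pixel population time variation, cohort
attrition, or geocoding error in the contact coordinates. Passing tests
therefore demonstrate that the statistics behave correctly on surfaces
with the documented structural features (decay, hard cutoff, near-field
spikes, heavy tails, persistence), not that any particular real surface
has those features to the same degree.

## What the fixed-seed checks show

On default-scenario studies the package reproduces the qualitative
findings the metrics were designed to surface: an elevated-PCV annulus at
the cutoff radius versus the interior; near-release PCV above the
grid-wide median; stayer year-over-year correlation exceeding mover
correlation by more than 0.1 at 500 transitions; day/night correlation
rising as the day-care placement radius shrinks; and a weak
population–toxicity correlation. Problem sizes (120×120 px, 6 years,
100–150 households; ≤ 25×25 grids for the brute-force oracle
comparisons) are desk-scale choices that keep the whole suite in seconds
while leaving every window size, truncation case and undefined state
exercised.

## Known limitations

* Square, axis-aligned neighbourhoods only (no circular or
  kernel-weighted windows), matching the nested-square design of the NCV.
* No CRS reprojection; inputs must share one projected grid.
* Correlations are pooled Pearson; no clustered or repeated-measures
  adjustment.
* The day/night analysis weights each wave equally and models no time
  budget (hours at day care vs home).
* Seed-to-seed spread of the population–toxicity correlation is wide at
  25 sites on a 120×120 grid; the fixed-seed invariant band (−0.05, 0.35)
  reflects that desk-scale variance.
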