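# contextcv

Sensitivity analyses for spatio-temporal uncertainty when linking
point-located individuals to gridded contextual exposure data.

A common design in environmental health research joins a cohort of
georeferenced people (points) to modelled context data published on a
regular grid (polygons) — for example, annual air-toxicity screening
scores on 0.5-mile pixels. That join is uncertain in several distinct
ways: the point may be geolocated to the wrong pixel, the relevant
"neighbourhood" may be larger than one pixel, the context changes from
year to year (and people move), and people are not at their residence all
day. `contextcv` quantifies each of these with a per-pixel
coefficient-of-variation statistic, links cohort contact records to the
grid, and ships a synthetic surface-and-cohort generator so the whole
pipeline is testable without restricted cohort data or bulk downloads.

## The statistics

For pixel *i* with value est<sub>i</sub>:

* **Positional CV** — `PCV_i = SD(est of i and its neighbours) / est_i`,
  by default the 3×3 window around *i*. High PCV: a small geolocation
  error changes the assigned value a lot.
* **Neighbourhood-size CV** —
  `NCV_i = SD(mean over nested neighbourhoods) / est_i` over square
  neighbourhoods of 1, 9, 25, 49, 81 and 361 pixels. High NCV: results
  depend on the analyst's choice of neighbourhood extent.
* **Life-course CV** — `LCV_i = SD(est_i1 … est_in) / median(est_i1 … est_in)`
  across *n* years. High LCV: the year chosen for a cross-sectional
  linkage matters.
* **Day/night** — Pearson correlation between residence and day-care
  exposure within the same visit wave, on the log10(x+1) scale.

All SDs are population SDs (configurable via `ddof`); windows truncate at
grid edges and masked-out pixels; zero-denominator pixels are carried as
an explicit *undefined* state through binning, summaries and raster
nodata. All three metrics are invariant under rescaling the grid, but not
under adding a constant.

## Worked example

```python
import numpy as np
import contextcv as cv

# a 3x3 grid with values 1..9
grid = cv.ContextGrid(spec=cv.GridSpec(3, 3),
                      toxicity=np.arange(1.0, 10.0).reshape(3, 3))
pcv = cv.pcv_surface(grid)
print(round(pcv.values[1, 1], 4))        # 0.5164

# a full synthetic study: surfaces, population, cohort
study = cv.simulate_study(cv.ScenarioConfig(seed=42))
linkage = cv.link_contacts(study.contacts, study.stack)
print(linkage.status_counts())           # {'ok': 2400}

from contextcv.mobility import build_transitions, corr_by_group
tr = build_transitions(linkage, study.stack)
print(corr_by_group(tr, "exposure_from", "exposure_to", by=["moved"]))
#    moved    n         r transform
# 0  False  519  0.657250   log10p1
# 1   True   81  0.001247   log10p1
# 2    all  600  0.579810   log10p1
```

The PCV centre value 0.5164 is the population SD of 1..9 (2.582) divided
by the centre value 5. In the synthetic study, households that stayed put
show strongly correlated year-over-year exposure (r ≈ 0.66 on the log
scale) while movers' destinations are uncorrelated with their origins
(r ≈ 0.00) — the mover/stayer gap that makes residential-history data
matter for exposure assessment.

The same pipeline is available from the shell:

```sh
contextcv simulate --seed 42 --out-dir run/
contextcv pcv --grid 2003=run/toxicity_2003.asc --out run/pcv.asc --bins
contextcv link --contacts run/contacts.csv --grid 2003=run/toxicity_2003.asc ... --out run/linkage.csv
contextcv mobility --linkage run/linkage.csv --grid 2003=... --out-dir run/
contextcv report --transitions run/transitions.csv --day-night run/day_night.csv --out-dir run/
```

Every stage writes a JSON manifest (config, output digests, row
accounting) and is bit-reproducible given the seed.

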