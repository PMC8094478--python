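"""Published reference constants used as inputs and cross-checks.

The FLP (Family Life Project) visit-count table gives the number of
cohort contacts by visit month, state and location type; its margins are
the size target the synthetic cohort emulates and a consistency check for
linkage accounting (every contact is linked or flagged, never lost).
"""

from __future__ import annotations

import pandas as pd

from .metrics import NeighborhoodSpec

__all__ = [
    "flp_visit_counts",
    "flp_total_contacts",
    "neighborhood_sizes",
    "FLP_COHORT_N",
]

#: children in the FLP cohort
FLP_COHORT_N = 1292

# visit month -> (daycare NC, daycare PA, residence NC, residence PA)
_FLP_COUNTS = {
    "2": (599, 378, 636, 400),
    "6": (597, 377, 611, 403),
    "15": (635, 432, 662, 453),
    "24": (631, 421, 655, 455),
    "35": (626, 400, 654, 442),
    "48": (518, 330, 596, 409),
    "58/60": (418, 225, 607, 403),
}


def flp_visit_counts() -> pd.DataFrame:
    """FLP contact counts by visit month, location type and state (long form)."""
    rows = []
    for month, (dc_nc, dc_pa, res_nc, res_pa) in _FLP_COUNTS.items():
        rows += [
            {"visit_month": month, "location_type": "daycare", "state": "NC",
             "count": dc_nc},
            {"visit_month": month, "location_type": "daycare", "state": "PA",
             "count": dc_pa},
            {"visit_month": month, "location_type": "residence", "state": "NC",
             "count": res_nc},
            {"visit_month": month, "location_type": "residence", "state": "PA",
             "count": res_pa},
        ]
    return pd.DataFrame(rows)


def flp_total_contacts() -> int:
    """Total FLP data points: the sum over every stratum of the visit table."""
    return int(flp_visit_counts()["count"].sum())


def neighborhood_sizes(nb: NeighborhoodSpec | None = None) -> tuple[int, ...]:
    """Pixel counts of the default nested square neighbourhoods."""
    return (nb or NeighborhoodSpec()).sizes
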