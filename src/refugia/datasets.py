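"""Published reference data used for worked examples and arithmetic checks.

``gb_focal_species_counts`` holds the published per-species counts of
British protected areas classified as occupied, at risk, in situ refugium
and ex situ refugium for twelve threatened vascular plants (hectad-scale
screening against 2080 climate projections).  The counts are inputs to the
summary arithmetic only; the package recomputes every derived percentage.
"""

from __future__ import annotations

import pandas as pd

from .classify import SpeciesSummaryRow

__all__ = ["gb_focal_species_counts", "gb_focal_species_rows"]

_GB_COUNTS = [
    # species, occupied, at_risk, in_situ, ex_situ
    ("Adonis annua", 192, 110, 82, 751),
    ("Turritis glabra", 295, 235, 60, 283),
    ("Cerastium alpinum", 63, 9, 54, 109),
    ("Carex ericetorum", 200, 190, 10, 202),
    ("Dryas octopetala", 87, 30, 57, 40),
    ("Galeopsis angustifolia", 545, 322, 223, 1635),
    ("Juniperus communis", 1482, 711, 771, 654),
    ("Mertensia maritima", 45, 21, 24, 45),
    ("Bistorta vivipara", 402, 100, 302, 249),
    ("Ranunculus tripartitus", 138, 109, 29, 112),
    ("Silene conica", 148, 102, 46, 87),
    ("Spiranthes romanzoffiana", 13, 13, 0, 27),
]


def gb_focal_species_counts() -> pd.DataFrame:
    """The published GB screening counts as a DataFrame."""
    return pd.DataFrame(
        _GB_COUNTS,
        columns=["species_id", "n_occupied", "n_at_risk", "n_in_situ", "n_ex_situ"],
    )


def gb_focal_species_rows() -> list[SpeciesSummaryRow]:
    """The same counts as summary rows, with % at risk recomputed (1 dp)."""
    rows = []
    for sid, occ, risk, insitu, exsitu in _GB_COUNTS:
        rows.append(
            SpeciesSummaryRow(
                species_id=sid,
                n_occupied=occ,
                n_at_risk=risk,
                n_in_situ=insitu,
                n_ex_situ=exsitu,
                pct_at_risk=round(100.0 * risk / occ, 1) if occ else None,
            )
        )
    return rows
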