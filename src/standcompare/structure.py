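"""Forest structure metrics: basal area per hectare and annualized change.

Basal area (BA, m2/ha) is the cross-sectional area of stems at breast height
per unit ground area, the standard plot-inventory proxy for standing biomass.
Because trees (>= 10 cm DBH) and saplings (2.5-10 cm DBH) are censused in
circles of different area, per-hectare BA is computed separately per stratum
and the two components summed.  Shrubs and lianas are never included in BA
(measurement consistency); they do enter biodiversity pools.

Stratum areas are computed from the dialect radii at full double precision
(pi * r^2), not from rounded presentation values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .inventory import (
    CANOPY_LIFEFORMS,
    ForestVisit,
    Lifeform,
    PlotGeometry,
    stem_protocol_issues,
)

M2_PER_HA = 10_000.0


@dataclass(frozen=True)
class BasalAreaResult:
    forest_id: str
    visit_year: int
    ba_per_ha: float
    tree_component: float
    sapling_component: float
    n_plots: int
    n_stems_used: int


@dataclass(frozen=True)
class ChangeEstimate:
    """Annualized relative change of a metric between two visits."""

    forest_id: str
    metric: str
    value_1: float
    value_2: float
    year_1: int
    year_2: int
    annualized: float
    convention: str


def stem_basal_area(dbh_cm: float) -> float:
    """Cross-sectional area (m2) of one stem: A = pi * DBH^2 / 4."""
    if not (dbh_cm > 0 and math.isfinite(dbh_cm)):
        raise ValueError(f"dbh must be positive and finite, got {dbh_cm}")
    return math.pi * (dbh_cm / 100.0) ** 2 / 4.0


def forest_basal_area(
    visit: ForestVisit, geometry: PlotGeometry | None = None
) -> BasalAreaResult:
    """Per-hectare basal area of one forest-visit.

    Tree/palm stems are summed over the tree stratum (area = n_plots x
    tree-circle area); sapling-lifeform stems over the sapling stratum.
    Stems recorded outside their lifeform's stratum are field errors and are
    excluded, as are shrubs and lianas.  Reference-dialect plots have a
    single stratum over the full 0.1 ha; tree and sapling components are
    still reported separately by size, over that common area.
    """
    geometry = geometry or visit.geometry
    if geometry.dialect != visit.dialect:
        raise ValueError(
            f"geometry dialect {geometry.dialect!r} != visit dialect {visit.dialect!r}"
        )
    if visit.n_plots < 1:
        raise ValueError(f"{visit.forest_id}/{visit.visit_year}: visit has no plots")

    tree_sum = 0.0
    sapling_sum = 0.0
    n_used = 0
    for stem in visit.stems:
        if stem.lifeform in CANOPY_LIFEFORMS:
            pass
        elif stem.lifeform is Lifeform.SAPLING:
            pass
        else:  # shrub / liana: never in BA
            continue
        if stem_protocol_issues(stem, geometry):
            continue  # out-of-stratum field error, flagged upstream
        if stem.dbh_cm >= geometry.tree_dbh_min_cm:
            tree_sum += stem_basal_area(stem.dbh_cm)
        else:
            sapling_sum += stem_basal_area(stem.dbh_cm)
        n_used += 1

    if geometry.is_reference:
        tree_area_ha = sapling_area_ha = visit.n_plots * geometry.total_area_m2 / M2_PER_HA
    else:
        tree_area_ha = visit.n_plots * geometry.tree_stratum_area_m2 / M2_PER_HA
        sapling_area_ha = visit.n_plots * geometry.sapling_stratum_area_m2 / M2_PER_HA

    tree_component = tree_sum / tree_area_ha
    sapling_component = sapling_sum / sapling_area_ha
    return BasalAreaResult(
        forest_id=visit.forest_id,
        visit_year=visit.visit_year,
        ba_per_ha=tree_component + sapling_component,
        tree_component=tree_component,
        sapling_component=sapling_component,
        n_plots=visit.n_plots,
        n_stems_used=n_used,
    )


def annualized_change(
    value_1: float,
    value_2: float,
    year_1: int,
    year_2: int,
    convention: str = "simple",
) -> float:
    """Annualized relative change of a metric between two years.

    ``simple``: ((v2 - v1) / v1) / (y2 - y1) — relative change per year.
    ``compound``: (v2 / v1)^(1 / (y2 - y1)) - 1 — constant yearly rate.

    Both are 0 iff the metric is unchanged, positive for growth and negative
    for decline.
    """
    if year_2 <= year_1:
        raise ValueError(f"year_2 ({year_2}) must be after year_1 ({year_1})")
    if not value_1 > 0:
        raise ValueError(f"value_1 must be positive, got {value_1}")
    if value_2 < 0:
        raise ValueError(f"value_2 must be non-negative, got {value_2}")
    span = year_2 - year_1
    if convention == "simple":
        return ((value_2 - value_1) / value_1) / span
    if convention == "compound":
        return (value_2 / value_1) ** (1.0 / span) - 1.0
    raise ValueError(f"unknown convention {convention!r}")


def change_estimate(
    forest_id: str,
    metric: str,
    value_1: float,
    value_2: float,
    year_1: int,
    year_2: int,
    convention: str = "simple",
) -> ChangeEstimate:
    return ChangeEstimate(
        forest_id=forest_id,
        metric=metric,
        value_1=value_1,
        value_2=value_2,
        year_1=year_1,
        year_2=year_2,
        annualized=annualized_change(value_1, value_2, year_1, year_2, convention),
        convention=convention,
    )
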