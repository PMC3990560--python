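"""Regional intercomparison: distance/elevation-weighted z-scores.

Forests differ in potential structure and biodiversity with climate,
elevation and species pool, so raw metric values are not comparable across
sites.  The intercomparison metric standardizes a forest's value against its
geographic neighborhood instead: for each focal forest, every other forest
(or every old-growth reference plot, in reference mode) within a "total
distance" cutoff contributes to an inverse-square-distance-weighted mean and
standard deviation, and the focal value is reported as a z-score against
that local distribution.

Total distance combines great-circle distance (haversine, Earth radius
6371 km) in km with absolute elevation difference in m as
``sqrt(geo_km^2 + elev_m^2)`` — deliberately mixed units, equating 1 m of
altitude with 1 km of horizontal distance (roughly equal temperature
effects at mid latitudes).  The default neighborhood cutoff is 1000 of
these units, inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inventory import Site, ValidationError

EARTH_RADIUS_KM = 6371.0
DEFAULT_CUTOFF_UNITS = 1000.0
DEFAULT_MIN_NEIGHBORS = 2


@dataclass(frozen=True)
class TotalDistance:
    """Geographic + elevation separation of two sites, in mixed units."""

    geo_km: float
    elev_m: float
    total: float


@dataclass(frozen=True)
class NeighborhoodStandardization:
    """A focal value standardized against its distance-weighted neighbors.

    ``z`` is NaN with a ``missing_reason`` when the neighborhood is too
    small or degenerate (zero weighted SD with the focal value off-center).
    """

    focal_id: str
    metric: str
    focal_value: float
    n_neighbors: int
    weighted_mean: float
    weighted_sd: float
    z: float
    neighbor_table: tuple[tuple[str, float, float], ...] = ()
    missing_reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.missing_reason is not None


def haversine_km(
    lat1: float, lon1: float, lat2: float, lon2: float,
    radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Great-circle distance between two points in decimal degrees."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} out of [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude {lon} out of [-180, 180]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = math.radians(lat2 - lat1)
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return radius_km * 2.0 * math.asin(min(1.0, math.sqrt(a)))


def total_distance(
    site_a: Site, site_b: Site, missing_elevation: str = "error"
) -> TotalDistance:
    """Combined geographic/elevation separation (1 m altitude ~ 1 km)."""
    geo = haversine_km(site_a.latitude, site_a.longitude,
                       site_b.latitude, site_b.longitude)
    elev_a, elev_b = site_a.elevation_m, site_b.elevation_m
    if math.isnan(elev_a) or math.isnan(elev_b):
        if missing_elevation == "zero":
            warnings.warn(
                f"missing elevation for {site_a.site_id}/{site_b.site_id}; "
                "treating elevation difference as 0"
            )
            elev = 0.0
        else:
            raise ValidationError(
                f"missing elevation for {site_a.site_id} or {site_b.site_id}"
            )
    else:
        elev = abs(elev_a - elev_b)
    return TotalDistance(geo_km=geo, elev_m=elev, total=math.hypot(geo, elev))


def build_neighborhood(
    focal_id: str,
    focal_value: float,
    focal_site: Site,
    candidates: Sequence[tuple[str, float, Site]],
    cutoff: float = DEFAULT_CUTOFF_UNITS,
    exclude_self: bool = True,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
    metric: str = "",
) -> NeighborhoodStandardization:
    """Standardize one focal value against distance-weighted candidates.

    Neighbors are candidates with ``0 < total distance <= cutoff``; weights
    are total-distance^-2, normalized to sum to 1.  The weighted SD uses the
    normalized-weight population form ``sqrt(sum w_i (v_i - mu)^2)``, which
    makes z invariant under common shifts and positive rescalings of all
    values.  Candidates at distance exactly 0 (co-located) would carry
    infinite weight and are excluded with a warning.
    """
    if not math.isfinite(focal_value):
        raise ValidationError(f"{focal_id}: focal value must be finite")
    ids, dists, values = [], [], []
    for cand_id, value, site in candidates:
        if exclude_self and cand_id == focal_id:
            continue
        td = total_distance(focal_site, site).total
        if td == 0.0:
            warnings.warn(
                f"candidate {cand_id} is co-located with focal {focal_id} "
                "(total distance 0); excluded from the neighborhood"
            )
            continue
        if td > cutoff:
            continue
        if not math.isfinite(value):
            raise ValidationError(f"candidate {cand_id}: value must be finite")
        ids.append(cand_id)
        dists.append(td)
        values.append(value)

    n = len(ids)
    if n < min_neighbors:
        return NeighborhoodStandardization(
            focal_id=focal_id, metric=metric, focal_value=focal_value,
            n_neighbors=n, weighted_mean=float("nan"), weighted_sd=float("nan"),
            z=float("nan"),
            missing_reason=f"insufficient neighborhood ({n} < {min_neighbors})",
        )

    d = np.asarray(dists)
    v = np.asarray(values)
    w = d**-2.0
    w = w / w.sum()
    mean = float(w @ v)
    sd = float(math.sqrt(w @ (v - mean) ** 2))
    table = tuple(zip(ids, (float(x) for x in d), (float(x) for x in w)))
    # an SD at rounding-noise level is a degenerate (all-equal) neighborhood
    tol = 1e-12 * max(1.0, abs(mean), float(np.max(np.abs(v))))
    if sd > tol:
        z = (focal_value - mean) / sd
        reason = None
    elif abs(focal_value - mean) <= tol:
        z, reason = 0.0, None
        sd = 0.0
    else:
        z, reason = float("nan"), "zero weighted SD with focal value off-center"
        sd = 0.0
    return NeighborhoodStandardization(
        focal_id=focal_id, metric=metric, focal_value=focal_value,
        n_neighbors=n, weighted_mean=mean, weighted_sd=sd, z=z,
        neighbor_table=table, missing_reason=reason,
    )


def intercompare_all(
    metric_table: pd.DataFrame,
    sites: Mapping[str, Site],
    mode: str = "regional",
    reference_table: pd.DataFrame | None = None,
    metric: str = "",
    cutoff: float = DEFAULT_CUTOFF_UNITS,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
) -> list[NeighborhoodStandardization]:
    """Standardize every forest in ``metric_table`` against its neighborhood.

    ``metric_table`` needs columns ``forest_id``, ``site_id``, ``value``
    (one row per forest — pass each forest's current visit only, so a forest
    is never compared against itself across time).  In ``regional`` mode the
    candidate pool is the table itself (self excluded per forest); in
    ``reference`` mode it is ``reference_table`` (same columns).  Forests
    with too-small neighborhoods are returned with a missing reason, never
    dropped.
    """
    for col in ("forest_id", "site_id", "value"):
        if col not in metric_table.columns:
            raise ValidationError(f"metric_table missing column {col!r}")
    if metric_table["forest_id"].duplicated().any():
        dups = sorted(metric_table.loc[metric_table["forest_id"].duplicated(), "forest_id"])
        raise ValidationError(f"duplicated forest ids in metric table: {dups}")
    if mode == "regional":
        cand_df = metric_table
        exclude_self = True
    elif mode == "reference":
        if reference_table is None:
            raise ValidationError("reference mode requires a reference_table")
        cand_df = reference_table
        exclude_self = False
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    def site_of(site_id: str) -> Site:
        try:
            return sites[site_id]
        except KeyError:
            raise ValidationError(f"no site {site_id!r} in the site table") from None

    candidates = [
        (str(r.forest_id), float(r.value), site_of(str(r.site_id)))
        for r in cand_df.itertuples(index=False)
    ]
    results = []
    for r in metric_table.itertuples(index=False):
        results.append(
            build_neighborhood(
                focal_id=str(r.forest_id),
                focal_value=float(r.value),
                focal_site=site_of(str(r.site_id)),
                candidates=candidates,
                cutoff=cutoff,
                exclude_self=exclude_self,
                min_neighbors=min_neighbors,
                metric=metric,
            )
        )
    return results


def standardizations_frame(
    results: Sequence[NeighborhoodStandardization], mode: str
) -> pd.DataFrame:
    """Tabular form of a batch of standardizations (intercomparison.csv)."""
    return pd.DataFrame(
        [
            {"forest_id": r.focal_id, "metric": r.metric, "mode": mode,
             "focal_value": r.focal_value, "n_neighbors": r.n_neighbors,
             "weighted_mean": r.weighted_mean, "weighted_sd": r.weighted_sd,
             "z": r.z, "missing_reason": r.missing_reason or ""}
            for r in results
        ]
    )
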