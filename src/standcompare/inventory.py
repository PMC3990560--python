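"""Domain model, delimited-text I/O and validation for forest-plot inventories.

The data model mirrors the field protocol of community-forestry monitoring
networks.  A *forest-visit* (one forest measured in one calendar year) is the
unit of all metric computation.  Each visit consists of plots censused in two
nested strata:

* **tree stratum** — all trees and palms with DBH >= 10 cm, measured within a
  large circle (10 m radius in the standard dialect);
* **sapling stratum** — tree saplings with 2.5 <= DBH < 10 cm plus all shrubs
  and lianas >= 2.5 cm DBH, measured within a small circle (3 m radius).

One regional dialect (``india_5m``) uses a single 5 m radius circle for both
strata and records stem *circumference* rather than diameter; circumferences
are converted on read (DBH = circumference / pi).  Old-growth *reference*
plots (``gentry_reference``) use a 0.1-ha layout of ten parallel 100 m2
transects ("subplots") in which every stem >= 2.5 cm DBH is measured and each
stem carries the index of its subplot.

All files are headered comma-separated text:

* ``sites.csv``: site_id, latitude, longitude, elevation_m
* ``plots.csv``: plot_id, forest_id, visit_year, dialect
* ``stems.csv``: stem_id, plot_id, forest_id, visit_year, species, lifeform,
  measure_cm, subplot_index (blank unless reference dialect)
* ``ratings.csv``: forest_id, visit_year, variable, code

The plot schema carries no site column; by convention ``site_id ==
forest_id`` unless the dialect config supplies an explicit mapping
(``{"forest": {"dialect": ..., "site_id": ...}}``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class SchemaError(ValueError):
    """An input file does not conform to its documented column schema."""


class ConfigError(ValueError):
    """A configuration value (e.g. an unknown dialect) is invalid."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class Lifeform(str, Enum):
    TREE = "tree"
    PALM = "palm"
    SAPLING = "sapling"
    SHRUB = "shrub"
    LIANA = "liana"


#: lifeforms that count as canopy trees throughout (palms are trees here)
CANOPY_LIFEFORMS = frozenset({Lifeform.TREE, Lifeform.PALM})

#: lifeforms excluded from basal area but included in biodiversity pools
NON_TREE_LIFEFORMS = frozenset({Lifeform.SHRUB, Lifeform.LIANA})


class SizeMeasure(str, Enum):
    DIAMETER = "diameter"
    CIRCUMFERENCE = "circumference"


@dataclass(frozen=True)
class PlotGeometry:
    """Per-dialect plot layout and measurement conventions.

    Circular dialects define one radius per stratum; the reference dialect
    instead defines a transect layout of ``n_subplots`` rectangles of
    ``subplot_area_m2`` each (total 0.1 ha) with a single census stratum.
    """

    dialect: str
    tree_stratum_radius_m: float | None
    sapling_stratum_radius_m: float | None
    size_measure: SizeMeasure
    tree_dbh_min_cm: float = 10.0
    sapling_dbh_min_cm: float = 2.5
    n_subplots: int | None = None
    subplot_area_m2: float | None = None

    @property
    def is_reference(self) -> bool:
        return self.n_subplots is not None

    @property
    def tree_stratum_area_m2(self) -> float:
        if self.is_reference:
            return self.total_area_m2
        return math.pi * self.tree_stratum_radius_m**2

    @property
    def sapling_stratum_area_m2(self) -> float:
        if self.is_reference:
            return self.total_area_m2
        return math.pi * self.sapling_stratum_radius_m**2

    @property
    def total_area_m2(self) -> float:
        """Full censused area of one plot (reference dialect only)."""
        if not self.is_reference:
            raise ConfigError(f"dialect {self.dialect!r} has no single plot area")
        return self.n_subplots * self.subplot_area_m2


DIALECTS: dict[str, PlotGeometry] = {
    "ifri_standard": PlotGeometry(
        dialect="ifri_standard",
        tree_stratum_radius_m=10.0,
        sapling_stratum_radius_m=3.0,
        size_measure=SizeMeasure.DIAMETER,
    ),
    "india_5m": PlotGeometry(
        dialect="india_5m",
        tree_stratum_radius_m=5.0,
        sapling_stratum_radius_m=5.0,
        size_measure=SizeMeasure.CIRCUMFERENCE,
    ),
    "gentry_reference": PlotGeometry(
        dialect="gentry_reference",
        tree_stratum_radius_m=None,
        sapling_stratum_radius_m=None,
        size_measure=SizeMeasure.DIAMETER,
        n_subplots=10,
        subplot_area_m2=100.0,
    ),
}


def get_geometry(dialect: str) -> PlotGeometry:
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise ConfigError(
            f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
        ) from None


@dataclass(frozen=True)
class Site:
    """A geographic location: WGS84 decimal degrees, elevation in metres."""

    site_id: str
    latitude: float
    longitude: float
    elevation_m: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"site {self.site_id}: latitude {self.latitude} out of [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"site {self.site_id}: longitude {self.longitude} out of [-180, 180]")
        if not math.isfinite(self.elevation_m):
            raise ValidationError(f"site {self.site_id}: elevation must be finite")


@dataclass(frozen=True)
class StemRecord:
    """One measured woody stem.  ``dbh_cm`` is always a diameter (any
    circumference conversion has already been applied); ``raw_measure_cm``
    keeps the value as recorded in the field."""

    stem_id: str
    plot_id: str
    species: str
    lifeform: Lifeform
    dbh_cm: float
    raw_measure_cm: float
    subplot_index: int | None = None

    def __post_init__(self) -> None:
        if not (self.dbh_cm > 0 and math.isfinite(self.dbh_cm)):
            raise ValidationError(f"stem {self.stem_id}: dbh must be positive and finite")
        if not self.species:
            raise ValidationError(f"stem {self.stem_id}: empty species label")
        if self.subplot_index is not None and not 1 <= self.subplot_index <= 10:
            raise ValidationError(f"stem {self.stem_id}: subplot_index must be 1-10")


@dataclass(frozen=True)
class ForestVisit:
    """A forest at one point in time — the unit of metric computation."""

    forest_id: str
    visit_year: int
    site_id: str
    dialect: str
    plots: frozenset[str]
    stems: tuple[StemRecord, ...]

    def __post_init__(self) -> None:
        if not 1900 <= self.visit_year <= 2100:
            raise ValidationError(
                f"{self.forest_id}: implausible visit_year {self.visit_year}"
            )
        orphans = {s.stem_id for s in self.stems if s.plot_id not in self.plots}
        if orphans:
            raise ValidationError(
                f"{self.forest_id}/{self.visit_year}: stems reference unknown plots: "
                f"{sorted(orphans)}"
            )

    @property
    def geometry(self) -> PlotGeometry:
        return get_geometry(self.dialect)

    @property
    def n_plots(self) -> int:
        return len(self.plots)


USER_RATING_VARIABLES = ("delta_density_user", "delta_area_user")
FORESTER_RATING_VARIABLES = ("density_forester", "diversity_forester")
RATING_CODES: dict[str, frozenset[int]] = {
    **{v: frozenset({-1, 0, 1}) for v in USER_RATING_VARIABLES},
    **{v: frozenset({-2, -1, 0, 1, 2}) for v in FORESTER_RATING_VARIABLES},
}


@dataclass(frozen=True)
class OrdinalRating:
    """A user's or forester's ordinal appraisal of one forest-visit."""

    forest_id: str
    visit_year: int
    variable: str
    code: int

    def __post_init__(self) -> None:
        if self.variable not in RATING_CODES:
            raise ValidationError(f"unknown rating variable {self.variable!r}")
        if self.code not in RATING_CODES[self.variable]:
            raise ValidationError(
                f"{self.variable}: code {self.code} outside "
                f"{sorted(RATING_CODES[self.variable])}"
            )


# ---------------------------------------------------------------------------
# species-label normalization
# ---------------------------------------------------------------------------

def normalize_species_label(raw: str) -> str:
    """Mechanically canonicalize a species label.

    Trims surrounding whitespace, collapses internal whitespace runs to a
    single space, and case-folds.  Deliberately does *no* fuzzy matching:
    distinct spellings remain distinct species.  Idempotent.
    """
    label = " ".join(str(raw).split()).casefold()
    if not label:
        raise ValidationError(f"species label {raw!r} is empty after normalization")
    return label


# ---------------------------------------------------------------------------
# stratum classification
# ---------------------------------------------------------------------------

def census_stratum(stem: StemRecord, geometry: PlotGeometry) -> str:
    """Size-based census stratum of a stem: ``"tree"`` or ``"sapling"``.

    Every stem at or above the sapling minimum belongs to exactly one
    stratum; the tree minimum itself (10.0 cm) falls in the tree stratum.
    """
    if stem.dbh_cm >= geometry.tree_dbh_min_cm:
        return "tree"
    if stem.dbh_cm >= geometry.sapling_dbh_min_cm:
        return "sapling"
    raise ValidationError(
        f"stem {stem.stem_id}: dbh {stem.dbh_cm} cm below the census minimum "
        f"({geometry.sapling_dbh_min_cm} cm)"
    )


def stem_protocol_issues(stem: StemRecord, geometry: PlotGeometry) -> list[str]:
    """Protocol-consistency problems for one stem (empty list if clean).

    Trees/palms must sit in the tree stratum; sapling-lifeform stems in the
    sapling stratum; shrubs and lianas anywhere at or above the sapling
    minimum.  Out-of-stratum stems are field errors: they are flagged here
    and excluded from structure metrics rather than silently reassigned.
    """
    issues: list[str] = []
    if stem.dbh_cm < geometry.sapling_dbh_min_cm:
        issues.append(
            f"stem {stem.stem_id}: dbh {stem.dbh_cm:.2f} cm below census minimum"
        )
        return issues
    if geometry.is_reference:
        # single-stratum transects census every stem >= 2.5 cm; the
        # tree/sapling lifeform split carries no protocol constraint there
        return issues
    stratum = census_stratum(stem, geometry)
    if stem.lifeform in CANOPY_LIFEFORMS and stratum != "tree":
        issues.append(
            f"stem {stem.stem_id}: {stem.lifeform.value} with dbh "
            f"{stem.dbh_cm:.2f} cm below the tree minimum "
            f"({geometry.tree_dbh_min_cm} cm)"
        )
    elif stem.lifeform is Lifeform.SAPLING and stratum != "sapling":
        issues.append(
            f"stem {stem.stem_id}: sapling with dbh {stem.dbh_cm:.2f} cm at or "
            f"above the tree minimum ({geometry.tree_dbh_min_cm} cm)"
        )
    return issues


def validate_visit(visit: ForestVisit) -> list[str]:
    """All protocol issues across a visit's stems (reference dialect adds a
    subplot-index requirement for small stems)."""
    geometry = visit.geometry
    issues: list[str] = []
    for stem in visit.stems:
        issues.extend(stem_protocol_issues(stem, geometry))
        if geometry.is_reference and stem.subplot_index is None:
            issues.append(
                f"stem {stem.stem_id}: reference-dialect stem without subplot_index"
            )
    return issues


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

SITE_COLUMNS = ("site_id", "latitude", "longitude", "elevation_m")
PLOT_COLUMNS = ("plot_id", "forest_id", "visit_year", "dialect")
STEM_COLUMNS = (
    "stem_id", "plot_id", "forest_id", "visit_year",
    "species", "lifeform", "measure_cm", "subplot_index",
)
RATING_COLUMNS = ("forest_id", "visit_year", "variable", "code")


@dataclass
class Inventory:
    """A validated inventory: visits, their sites, and non-fatal issues."""

    visits: list[ForestVisit]
    sites: dict[str, Site]
    issues: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.visits)

    def get(self, forest_id: str, visit_year: int) -> ForestVisit:
        for v in self.visits:
            if v.forest_id == forest_id and v.visit_year == visit_year:
                return v
        raise KeyError((forest_id, visit_year))


def _require_columns(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _read_csv(path, columns: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, columns, path)
    return df


def read_sites(path) -> dict[str, Site]:
    df = _read_csv(path, SITE_COLUMNS)
    sites: dict[str, Site] = {}
    for row in df.itertuples(index=False):
        sid = str(row.site_id)
        if sid in sites:
            raise ValidationError(f"{path}: duplicate site_id {sid!r}")
        sites[sid] = Site(
            site_id=sid,
            latitude=float(row.latitude),
            longitude=float(row.longitude),
            elevation_m=float(row.elevation_m),
        )
    return sites


def _resolve_dialect_config(
    dialect_config: Mapping[str, object] | None, forest_id: str
) -> tuple[str | None, str | None]:
    """(dialect override, site_id override) for one forest."""
    if not dialect_config or forest_id not in dialect_config:
        return None, None
    entry = dialect_config[forest_id]
    if isinstance(entry, str):
        return entry, None
    return entry.get("dialect"), entry.get("site_id")  # type: ignore[union-attr]


def read_inventory(
    stem_path,
    plot_path,
    site_path,
    dialect_config: Mapping[str, object] | None = None,
) -> Inventory:
    """Read and validate a full inventory from its three CSV files.

    Circumference-measured dialects are converted to DBH on read
    (``dbh = measure / pi``).  Protocol issues (out-of-stratum stems) are
    collected on ``Inventory.issues`` — reported, never silently dropped.
    Referential failures (stems pointing at unknown plots, unknown dialects,
    missing columns) raise.
    """
    sites = read_sites(site_path)
    plots_df = _read_csv(plot_path, PLOT_COLUMNS)
    stems_df = _read_csv(stem_path, STEM_COLUMNS)

    # visits are defined by the plot table
    visit_plots: dict[tuple[str, int], set[str]] = {}
    visit_dialect: dict[tuple[str, int], str] = {}
    plot_to_visit: dict[str, tuple[str, int]] = {}
    for row in plots_df.itertuples(index=False):
        key = (str(row.forest_id), int(row.visit_year))
        dialect_override, _ = _resolve_dialect_config(dialect_config, key[0])
        dialect = dialect_override or str(row.dialect)
        get_geometry(dialect)  # raises ConfigError if unknown
        prev = visit_dialect.setdefault(key, dialect)
        if prev != dialect:
            raise ConfigError(f"forest-visit {key}: conflicting dialects {prev!r}/{dialect!r}")
        pid = str(row.plot_id)
        if pid in plot_to_visit:
            raise ValidationError(f"{plot_path}: duplicate plot_id {pid!r}")
        plot_to_visit[pid] = key
        visit_plots.setdefault(key, set()).add(pid)

    visit_stems: dict[tuple[str, int], list[StemRecord]] = {k: [] for k in visit_plots}
    orphan_stems: list[str] = []
    issues: list[str] = []
    for row in stems_df.itertuples(index=False):
        key = (str(row.forest_id), int(row.visit_year))
        pid = str(row.plot_id)
        if key not in visit_plots or pid not in visit_plots[key]:
            orphan_stems.append(str(row.stem_id))
            continue
        geometry = get_geometry(visit_dialect[key])
        raw = float(row.measure_cm)
        if raw <= 0:
            raise ValidationError(f"stem {row.stem_id}: non-positive measure_cm {raw}")
        dbh = raw / math.pi if geometry.size_measure is SizeMeasure.CIRCUMFERENCE else raw
        try:
            lifeform = Lifeform(str(row.lifeform).strip().lower())
        except ValueError:
            raise ValidationError(
                f"stem {row.stem_id}: unknown lifeform {row.lifeform!r}"
            ) from None
        subplot = str(row.subplot_index).strip()
        stem = StemRecord(
            stem_id=str(row.stem_id),
            plot_id=pid,
            species=normalize_species_label(str(row.species)),
            lifeform=lifeform,
            dbh_cm=dbh,
            raw_measure_cm=raw,
            subplot_index=int(subplot) if subplot else None,
        )
        visit_stems[key].append(stem)

    if orphan_stems:
        raise ValidationError(
            f"stems reference unknown plots or visits: {sorted(orphan_stems)}"
        )

    visits: list[ForestVisit] = []
    for key in sorted(visit_plots):
        forest_id, visit_year = key
        _, site_override = _resolve_dialect_config(dialect_config, forest_id)
        site_id = site_override or forest_id
        if site_id not in sites:
            raise ValidationError(
                f"forest {forest_id!r}: no site {site_id!r} in the site table"
            )
        visit = ForestVisit(
            forest_id=forest_id,
            visit_year=visit_year,
            site_id=site_id,
            dialect=visit_dialect[key],
            plots=frozenset(visit_plots[key]),
            stems=tuple(visit_stems[key]),
        )
        issues.extend(validate_visit(visit))
        visits.append(visit)

    return Inventory(visits=visits, sites=sites, issues=issues)


def write_inventory(inventory: Inventory, outdir) -> None:
    """Write sites.csv / plots.csv / stems.csv (round-trips with
    :func:`read_inventory`).  ``measure_cm`` is written as recorded."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"site_id": s.site_id, "latitude": s.latitude,
             "longitude": s.longitude, "elevation_m": s.elevation_m}
            for s in inventory.sites.values()
        ],
        columns=list(SITE_COLUMNS),
    ).to_csv(outdir / "sites.csv", index=False)
    plot_rows = []
    stem_rows = []
    for v in inventory.visits:
        for pid in sorted(v.plots):
            plot_rows.append(
                {"plot_id": pid, "forest_id": v.forest_id,
                 "visit_year": v.visit_year, "dialect": v.dialect}
            )
        for s in v.stems:
            stem_rows.append(
                {"stem_id": s.stem_id, "plot_id": s.plot_id,
                 "forest_id": v.forest_id, "visit_year": v.visit_year,
                 "species": s.species, "lifeform": s.lifeform.value,
                 "measure_cm": s.raw_measure_cm,
                 "subplot_index": "" if s.subplot_index is None else s.subplot_index}
            )
    pd.DataFrame(plot_rows, columns=list(PLOT_COLUMNS)).to_csv(
        outdir / "plots.csv", index=False
    )
    pd.DataFrame(stem_rows, columns=list(STEM_COLUMNS)).to_csv(
        outdir / "stems.csv", index=False
    )


def read_ratings(path) -> list[OrdinalRating]:
    df = _read_csv(path, RATING_COLUMNS)
    return [
        OrdinalRating(
            forest_id=str(r.forest_id),
            visit_year=int(r.visit_year),
            variable=str(r.variable),
            code=int(r.code),
        )
        for r in df.itertuples(index=False)
    ]


def write_ratings(ratings: Iterable[OrdinalRating], path) -> None:
    pd.DataFrame(
        [
            {"forest_id": r.forest_id, "visit_year": r.visit_year,
             "variable": r.variable, "code": r.code}
            for r in ratings
        ],
        columns=list(RATING_COLUMNS),
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sanity filter
# ---------------------------------------------------------------------------

def apply_sanity_filter(
    visit: ForestVisit, max_dbh_cm: float = 1000.0
) -> tuple[ForestVisit, list[dict]]:
    """Flag and exclude stems with implausibly large DBH.

    Field data occasionally records a circumference or a height in the DBH
    column; any stem with DBH above ``max_dbh_cm`` (default 10 m) is excluded
    and listed in the returned report.  Pass ``math.inf`` to disable.
    """
    if not max_dbh_cm > 0:
        raise ValidationError("max_dbh_cm must be positive")
    kept = tuple(s for s in visit.stems if s.dbh_cm <= max_dbh_cm)
    report = [
        {"stem_id": s.stem_id, "dbh_cm": s.dbh_cm,
         "reason": f"dbh {s.dbh_cm:.1f} cm exceeds sanity threshold {max_dbh_cm:g} cm"}
        for s in visit.stems
        if s.dbh_cm > max_dbh_cm
    ]
    return replace(visit, stems=kept), report
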