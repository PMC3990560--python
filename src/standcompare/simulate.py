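"""Synthetic landscapes, forest visits, reference plots and ratings.

The generator produces complete inventories with known ground truth so
every pipeline stage — readers, basal area, rarefaction, intercomparison,
assessment statistics — can be exercised and calibrated with zero external
input.  It emulates the structural features of multi-country community
forest monitoring data:

* sites clustered in a few widely separated regions, with within-cluster
  scatter of tens of km and moderate elevation spread, so neighborhoods at
  the 1000-unit total-distance cutoff fall within clusters;
* a smooth regional field for stem density and species-pool size plus an
  independent per-forest deviation (the latent "condition" that parameter
  recovery tests try to re-identify from intercomparison z-scores);
* log-series species abundances and truncated-exponential stem sizes per
  census stratum;
* 0.1-ha ten-subplot reference transects with an optional old-growth
  "uplift" of density and size;
* ordinal ratings produced by thresholding latent condition plus a shared
  per-rater "halo" component plus independent noise.

It is test scaffolding, not a calibrated ecological simulator: no climate,
soil, spatial autocorrelation of composition, or succession dynamics.
All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .inventory import (
    ForestVisit,
    Inventory,
    Lifeform,
    OrdinalRating,
    Site,
    StemRecord,
    ValidationError,
)

KM_PER_DEG_LAT = 111.2


@dataclass(frozen=True)
class LandscapeSpec:
    """Geometry and latent structure of a synthetic landscape."""

    n_forests: int = 100
    n_clusters: int = 4
    cluster_spread_km: float = 50.0
    elevation_range_m: tuple[float, float] = (200.0, 2200.0)
    elevation_spread_m: float = 120.0
    #: log-scale regional gradient of stem density per degree of latitude
    density_gradient_per_deg: float = 0.01
    #: log-scale regional gradient of species-pool size per degree
    richness_gradient_per_deg: float = 0.01
    #: SD of the per-forest log-scale deviation (the recoverable signal)
    effect_sd: float = 0.4
    #: multiplier applied to the effect when it acts on species-pool size;
    #: > 1 makes richness vary more widely across forests than density,
    #: matching the order-of-magnitude spread of rarefied richness seen in
    #: real multi-biome inventories
    richness_effect_scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_forests >= self.n_clusters >= 1:
            raise ValidationError("need n_forests >= n_clusters >= 1")
        if min(self.cluster_spread_km, self.elevation_spread_m, self.effect_sd) < 0:
            raise ValidationError("all spreads must be non-negative")


@dataclass(frozen=True)
class CommunitySpec:
    """Composition and size structure of a synthetic stem community."""

    species_pool: int = 60
    #: log-series shape parameter (closer to 1 = more rare species)
    abundance_theta: float = 0.98
    #: expected stems per plot, all lifeforms (tree stratum + sapling stratum)
    stem_density: float = 35.0
    #: exponential DBH scale above the 10 cm tree minimum
    tree_dbh_scale_cm: float = 12.0
    #: truncated-exponential DBH scale within the 2.5-10 cm sapling band
    sapling_dbh_scale_cm: float = 2.5
    lifeform_mix: dict[str, float] = field(
        default_factory=lambda: {
            "tree": 0.50, "palm": 0.05, "sapling": 0.30,
            "shrub": 0.08, "liana": 0.07,
        }
    )

    def __post_init__(self) -> None:
        total = sum(self.lifeform_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValidationError(f"lifeform_mix must sum to 1, got {total}")
        if self.species_pool < 2 or self.stem_density <= 0:
            raise ValidationError("species_pool >= 2 and stem_density > 0 required")
        if not 0 < self.abundance_theta < 1:
            raise ValidationError("abundance_theta must be in (0, 1)")


def _log_series_probs(n_species: int, theta: float) -> np.ndarray:
    k = np.arange(1, n_species + 1, dtype=float)
    p = theta**k / k
    return p / p.sum()


def _draw_species(rng: np.random.Generator, n: int, pool: int, theta: float) -> np.ndarray:
    probs = _log_series_probs(pool, theta)
    # shuffle abundance ranks onto species ids so plots differ in identity
    return rng.choice(pool, size=n, p=probs)


def generate_landscape(
    spec: LandscapeSpec,
) -> tuple[dict[str, Site], dict[str, float], dict[str, dict[str, float]]]:
    """Clustered sites plus per-forest latent effects and regional fields.

    Returns ``(sites, effects, fields)``: sites keyed by forest id (the
    site-id convention), the latent per-forest log-scale deviations, and
    per-forest regional field values ``{"log_density": ..., "log_richness":
    ...}`` against which the deviations are applied.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    # cluster centers far apart: distinct longitudes 40 deg apart (~4000 km)
    center_lat = rng.uniform(-20.0, 35.0, spec.n_clusters)
    center_lon = -120.0 + 40.0 * np.arange(spec.n_clusters) + rng.uniform(-5, 5, spec.n_clusters)
    lo, hi = spec.elevation_range_m
    center_elev = rng.uniform(lo, hi, spec.n_clusters)

    assignment = np.sort(np.arange(spec.n_forests) % spec.n_clusters)
    sites: dict[str, Site] = {}
    effects: dict[str, float] = {}
    fields: dict[str, dict[str, float]] = {}
    for i in range(spec.n_forests):
        c = assignment[i]
        fid = f"F{i + 1:03d}"
        dlat = rng.normal(0.0, spec.cluster_spread_km) / KM_PER_DEG_LAT
        lat = float(np.clip(center_lat[c] + dlat, -89.0, 89.0))
        dlon = rng.normal(0.0, spec.cluster_spread_km) / (
            KM_PER_DEG_LAT * max(0.2, math.cos(math.radians(lat)))
        )
        lon = float(center_lon[c] + dlon)
        elev = float(max(0.0, center_elev[c] + rng.normal(0.0, spec.elevation_spread_m)))
        sites[fid] = Site(site_id=fid, latitude=lat, longitude=lon, elevation_m=elev)
        effect = float(rng.normal(0.0, spec.effect_sd))
        effects[fid] = effect
        fields[fid] = {
            "log_density": spec.density_gradient_per_deg * lat
            - 1e-4 * (elev - 0.5 * (lo + hi)),
            "log_richness": spec.richness_gradient_per_deg * lat
            - 1e-4 * (elev - 0.5 * (lo + hi)),
        }
    return sites, effects, fields


def generate_visit(
    site: Site,
    community: CommunitySpec,
    n_plots: int,
    dialect: str = "ifri_standard",
    effect: float = 0.0,
    seed: int = 0,
    forest_id: str | None = None,
    visit_year: int = 2010,
    log_density_field: float = 0.0,
    log_richness_field: float = 0.0,
    richness_effect: float | None = None,
) -> ForestVisit:
    """One forest-visit sampled under the census rules of its dialect.

    The latent ``effect`` multiplies stem density and species-pool size on
    the log scale, so a positive effect raises both basal area and expected
    rarefied richness — the sign that intercomparison z-scores should
    recover.  Stems follow the stratum protocol: trees/palms >= 10 cm DBH,
    saplings 2.5-10 cm, shrubs/lianas >= 2.5 cm.
    """
    if n_plots < 1:
        raise ValidationError("n_plots must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    forest_id = forest_id or site.site_id
    if richness_effect is None:
        richness_effect = effect
    density = community.stem_density * math.exp(log_density_field + effect)
    pool = max(
        2, round(community.species_pool * math.exp(log_richness_field + richness_effect))
    )
    forms = list(community.lifeform_mix)
    probs = np.array([community.lifeform_mix[f] for f in forms])

    plot_ids = [f"{forest_id}-{visit_year}-p{j + 1:02d}" for j in range(n_plots)]
    stems: list[StemRecord] = []
    counter = 0
    for pid in plot_ids:
        n_stems = rng.poisson(density)
        if n_stems == 0:
            continue
        lifeforms = rng.choice(len(forms), size=n_stems, p=probs)
        species = _draw_species(rng, n_stems, pool, community.abundance_theta)
        for lf_idx, sp in zip(lifeforms, species):
            lf = Lifeform(forms[lf_idx])
            if lf in (Lifeform.TREE, Lifeform.PALM):
                dbh = 10.0 + float(rng.exponential(community.tree_dbh_scale_cm))
            else:
                # truncated exponential within [2.5, 10)
                u = rng.uniform()
                scale = community.sapling_dbh_scale_cm
                fmax = 1.0 - math.exp(-7.4 / scale)
                dbh = 2.5 - scale * math.log(1.0 - u * fmax)
            counter += 1
            if dialect == "india_5m":
                raw = dbh * math.pi  # recorded as circumference in the field
            else:
                raw = dbh
            stems.append(
                StemRecord(
                    stem_id=f"{forest_id}-{visit_year}-s{counter:05d}",
                    plot_id=pid,
                    species=f"species {sp + 1:04d}",
                    lifeform=lf,
                    dbh_cm=dbh,
                    raw_measure_cm=raw,
                )
            )
    return ForestVisit(
        forest_id=forest_id,
        visit_year=visit_year,
        site_id=site.site_id,
        dialect=dialect,
        plots=frozenset(plot_ids),
        stems=tuple(stems),
    )


def generate_reference_plot(
    community: CommunitySpec,
    uplift: float = 0.5,
    seed: int = 0,
    forest_id: str = "REF001",
    site_id: str | None = None,
    visit_year: int = 2010,
) -> ForestVisit:
    """A 0.1-ha ten-subplot reference transect (old-growth analogue).

    ``uplift`` inflates stem density, tree fraction and tree size on the
    log scale relative to the community baseline, emulating the higher
    standing stock and richness of minimally disturbed forests.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    site_id = site_id or forest_id
    plot_id = f"{forest_id}-{visit_year}-t01"
    pool = max(2, round(community.species_pool * math.exp(0.5 * uplift)))
    # expected stems per 100 m2 subplot, scaled from per-plot density over
    # the ~314 m2 tree circle + ~28 m2 sapling circle
    per_subplot = community.stem_density * 100.0 / 342.4 * math.exp(uplift)
    tree_frac = min(0.9, (community.lifeform_mix["tree"] + community.lifeform_mix["palm"])
                    * math.exp(0.3 * uplift))
    stems: list[StemRecord] = []
    counter = 0
    for sub in range(1, 11):
        n_stems = rng.poisson(per_subplot)
        if n_stems == 0:
            continue
        species = _draw_species(rng, n_stems, pool, community.abundance_theta)
        for sp in species:
            counter += 1
            if rng.uniform() < tree_frac:
                lf = Lifeform.TREE
                dbh = 10.0 + float(
                    rng.exponential(community.tree_dbh_scale_cm * math.exp(0.3 * uplift))
                )
            else:
                lf = Lifeform.SAPLING
                u = rng.uniform()
                scale = community.sapling_dbh_scale_cm
                fmax = 1.0 - math.exp(-7.4 / scale)
                dbh = 2.5 - scale * math.log(1.0 - u * fmax)
            stems.append(
                StemRecord(
                    stem_id=f"{forest_id}-{visit_year}-s{counter:05d}",
                    plot_id=plot_id,
                    species=f"species {sp + 1:04d}",
                    lifeform=lf,
                    dbh_cm=dbh,
                    raw_measure_cm=dbh,
                    subplot_index=sub,
                )
            )
    return ForestVisit(
        forest_id=forest_id,
        visit_year=visit_year,
        site_id=site_id,
        dialect="gentry_reference",
        plots=frozenset({plot_id}),
        stems=tuple(stems),
    )


def generate_ratings(
    true_effects: dict[str, float],
    halo: float = 0.5,
    noise: float = 1.0,
    seed: int = 0,
    visit_year: int = 2010,
) -> list[OrdinalRating]:
    """Ordinal ratings produced by thresholding a latent appraisal.

    Each forest's rater forms ``latent_v = effect + halo * g + noise *
    eps_v`` per variable, where ``g`` is a shared per-forest sentiment (the
    halo component) and ``eps_v`` is variable-specific noise.  User
    variables are cut into three codes at +-0.43 of the latent scale;
    forester variables into five codes at +-0.43 and +-1.28.
    """
    if not 0.0 <= halo <= 1.0:
        raise ValidationError("halo must be in [0, 1]")
    if noise < 0.0:
        raise ValidationError("noise must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    user_cuts = np.array([-0.43, 0.43])
    forester_cuts = np.array([-1.28, -0.43, 0.43, 1.28])
    ratings: list[OrdinalRating] = []
    for fid in sorted(true_effects):
        g = rng.normal()
        for variable in ("delta_density_user", "delta_area_user",
                         "density_forester", "diversity_forester"):
            latent = true_effects[fid] + halo * g + noise * rng.normal()
            if variable.endswith("_user"):
                code = int(np.searchsorted(user_cuts, latent)) - 1
            else:
                code = int(np.searchsorted(forester_cuts, latent)) - 2
            ratings.append(
                OrdinalRating(forest_id=fid, visit_year=visit_year,
                              variable=variable, code=code)
            )
    return ratings


@dataclass
class SimulatedDataset:
    """A complete synthetic study: inventories, ratings, and ground truth."""

    inventory: Inventory
    reference_inventory: Inventory
    ratings: list[OrdinalRating]
    effects: dict[str, float]
    revisit_drifts: dict[str, float]


def simulate_dataset(
    landscape: LandscapeSpec | None = None,
    community: CommunitySpec | None = None,
    n_plots: int = 10,
    dialect: str = "ifri_standard",
    revisit_fraction: float = 0.25,
    year_1: int = 2004,
    year_2: int = 2010,
    n_reference_per_cluster: int = 8,
    reference_uplift: float = 0.5,
    ratings_halo: float = 0.6,
    ratings_noise: float = 0.8,
    seed: int | None = None,
) -> SimulatedDataset:
    """Generate a full synthetic study from one root seed.

    Every forest is visited in ``year_2``; a fraction also has a baseline
    visit in ``year_1`` whose density differs by a random drift (so
    annualized change has known sign).  Reference transects are co-located
    with the site clusters, with an old-growth uplift.
    """
    landscape = landscape or LandscapeSpec()
    if seed is not None:
        landscape = LandscapeSpec(**{**landscape.__dict__, "seed": seed})
    community = community or CommunitySpec()
    root = np.random.SeedSequence(landscape.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(6)]
    sites, effects, fields = generate_landscape(landscape)
    rng = np.random.default_rng(np.random.SeedSequence(seeds[0]))

    visits: list[ForestVisit] = []
    drifts: dict[str, float] = {}
    forest_ids = sorted(sites)
    visit_seed_rng = np.random.default_rng(np.random.SeedSequence(seeds[1]))
    for fid in forest_ids:
        f = fields[fid]
        visits.append(
            generate_visit(
                sites[fid], community, n_plots, dialect,
                effect=effects[fid],
                richness_effect=effects[fid] * landscape.richness_effect_scale,
                seed=int(visit_seed_rng.integers(2**31)),
                forest_id=fid, visit_year=year_2,
                log_density_field=f["log_density"],
                log_richness_field=f["log_richness"],
            )
        )
        if rng.uniform() < revisit_fraction:
            drift = float(rng.normal(0.15, 0.25))
            drifts[fid] = drift
            visits.append(
                generate_visit(
                    sites[fid], community, n_plots, dialect,
                    effect=effects[fid] - drift,
                    richness_effect=(effects[fid] - drift) * landscape.richness_effect_scale,
                    seed=int(visit_seed_rng.integers(2**31)),
                    forest_id=fid, visit_year=year_1,
                    log_density_field=f["log_density"],
                    log_richness_field=f["log_richness"],
                )
            )

    # reference transects near each cluster: re-use a few forest locations,
    # jittered, so cutoff-1000 neighborhoods contain them
    ref_sites: dict[str, Site] = {}
    ref_visits: list[ForestVisit] = []
    ref_rng = np.random.default_rng(np.random.SeedSequence(seeds[2]))
    n_ref = n_reference_per_cluster * landscape.n_clusters
    anchors = ref_rng.choice(forest_ids, size=min(n_ref, len(forest_ids)), replace=False)
    for j, anchor in enumerate(sorted(anchors)):
        a = sites[anchor]
        rid = f"REF{j + 1:03d}"
        ref_sites[rid] = Site(
            site_id=rid,
            latitude=float(np.clip(a.latitude + ref_rng.normal(0, 0.1), -89, 89)),
            longitude=a.longitude + float(ref_rng.normal(0, 0.1)),
            elevation_m=max(0.0, a.elevation_m + float(ref_rng.normal(0, 50.0))),
        )
        ref_visits.append(
            generate_reference_plot(
                community, uplift=reference_uplift,
                seed=int(ref_rng.integers(2**31)),
                forest_id=rid, site_id=rid, visit_year=year_2,
            )
        )

    ratings = generate_ratings(
        effects, halo=ratings_halo, noise=ratings_noise,
        seed=seeds[3], visit_year=year_2,
    )
    return SimulatedDataset(
        inventory=Inventory(visits=visits, sites=sites),
        reference_inventory=Inventory(visits=ref_visits, sites=ref_sites),
        ratings=ratings,
        effects=effects,
        revisit_drifts=drifts,
    )
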