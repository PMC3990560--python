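"""Stem-based rarefied species richness and sampling-effort harmonization.

Raw species counts grow with sampling effort, so forests censused with
different numbers of plots or stems are not directly comparable.  The
estimator used throughout is individual-based rarefaction with replacement:
pool every stem of a forest-visit (all lifeforms), draw ``n_draw`` stems with
replacement, count unique species, repeat ``reps`` times and report the
median of the resulting distribution ("SR").

Two harmonized variants reduce a visit's *area* footprint to that of a
0.1-ha reference transect before rarefying:

* focal forests — each repetition first draws a small subset of plots
  (3 standard 10-m plots ~ 0.0942 ha; for the 5-m Indian dialect, 12 plots
  for trees/palms — the same tree-stratum area — plus 1 plot for the other
  lifeforms) and rarefies within that subset;
* reference plots — all stems >= 10 cm DBH enter every repetition, but
  stems below 10 cm are taken from one randomly chosen 100-m2 subplot per
  repetition, matching the ~85 m2 sapling area of 3 standard plots.

Randomness protocol: each estimate takes one root seed; repetition ``r``
uses an independent child stream (``SeedSequence.spawn``), so results do not
depend on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inventory import CANOPY_LIFEFORMS, ForestVisit, ValidationError

#: dialect-specific plot-subset sizes for harmonized focal richness
INDIA_TREE_PLOTS = 12
INDIA_OTHER_PLOTS = 1


@dataclass(frozen=True)
class RarefactionEstimate:
    """Median and distribution of unique-species counts over repeated draws.

    ``median_richness`` is NaN (with ``missing_reason``) for empty pools or
    visits with too few plots; the median of an even number of repetitions is
    the mean of the two central order statistics, so half-integers occur.
    """

    forest_id: str
    visit_year: int
    estimator: str
    median_richness: float
    q05: float
    q25: float
    q75: float
    q95: float
    n_draw: int
    reps: int
    seed: int
    pool_size: int
    missing_reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.missing_reason is not None


def pool_stems(visit: ForestVisit) -> list[str]:
    """Species labels of every stem in the visit, all lifeforms pooled.

    Unlike basal area, biodiversity pools include shrubs and lianas; plot
    structure is ignored.
    """
    return [s.species for s in visit.stems]


def _missing(visit: ForestVisit, estimator: str, n_draw, reps, seed, pool_size, reason):
    nan = float("nan")
    return RarefactionEstimate(
        forest_id=visit.forest_id, visit_year=visit.visit_year,
        estimator=estimator, median_richness=nan,
        q05=nan, q25=nan, q75=nan, q95=nan,
        n_draw=n_draw, reps=reps, seed=seed, pool_size=pool_size,
        missing_reason=reason,
    )


def _summarize(counts: np.ndarray, visit, estimator, n_draw, reps, seed, pool_size):
    q05, q25, q75, q95 = np.quantile(counts, [0.05, 0.25, 0.75, 0.95])
    return RarefactionEstimate(
        forest_id=visit.forest_id, visit_year=visit.visit_year,
        estimator=estimator, median_richness=float(np.median(counts)),
        q05=float(q05), q25=float(q25), q75=float(q75), q95=float(q95),
        n_draw=n_draw, reps=reps, seed=seed, pool_size=pool_size,
    )


def _rep_generators(seed: int, reps: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(reps)
    return [np.random.Generator(np.random.PCG64(c)) for c in children]


def _unique_count(codes: np.ndarray, rng: np.random.Generator, n_draw: int) -> int:
    draw = codes[rng.integers(0, codes.size, n_draw)]
    return int(np.unique(draw).size)


def rarefy_pool(
    labels, n_draw: int = 100, reps: int = 1000, seed: int = 0
) -> np.ndarray:
    """Unique-species counts for ``reps`` draws of ``n_draw`` stems with
    replacement from a pool of species labels.  Deterministic given the
    seed; the pool may be smaller than ``n_draw``."""
    codes = np.asarray(np.unique(list(labels), return_inverse=True)[1])
    if codes.size == 0:
        raise ValidationError("cannot rarefy an empty pool")
    counts = np.empty(reps, dtype=np.int64)
    for r, rng in enumerate(_rep_generators(seed, reps)):
        counts[r] = _unique_count(codes, rng, n_draw)
    return counts


def rarefied_richness(
    visit: ForestVisit,
    n_draw: int = 100,
    reps: int = 1000,
    seed: int = 0,
) -> RarefactionEstimate:
    """Median rarefied species richness of a visit's pooled stems.

    Pools smaller than ``n_draw`` remain computable (sampling is with
    replacement); forests with very few stems simply have genuinely low
    richness.  Deterministic given the seed.
    """
    pool = pool_stems(visit)
    if not pool:
        return _missing(visit, "sr100", n_draw, reps, seed, 0, "empty stem pool")
    counts = rarefy_pool(pool, n_draw, reps, seed)
    return _summarize(counts, visit, "sr100", n_draw, reps, seed, len(pool))


def harmonized_richness_focal(
    visit: ForestVisit,
    n_plots_subset: int = 3,
    n_draw: int = 100,
    reps: int = 1000,
    seed: int = 0,
) -> RarefactionEstimate:
    """Rarefied richness harmonized to a ~0.1-ha sampling footprint.

    Each repetition draws ``n_plots_subset`` plots without replacement
    (standard dialect), pools their stems and rarefies.  The 5-m Indian
    dialect instead draws 12 plots for trees and palms (equal tree-stratum
    area) and 1 independently chosen plot for all other lifeforms.  Plot
    subsets are drawn independently across repetitions.
    """
    estimator = f"sr100_{n_plots_subset}plot"
    dialect = visit.dialect
    plot_ids = sorted(visit.plots)
    if dialect == "india_5m":
        need = INDIA_TREE_PLOTS
    elif dialect == "ifri_standard":
        need = n_plots_subset
    else:
        raise ValidationError(
            f"harmonized focal richness undefined for dialect {dialect!r}"
        )
    if len(plot_ids) < need:
        return _missing(
            visit, estimator, n_draw, reps, seed, len(visit.stems),
            f"needs >= {need} plots, visit has {len(plot_ids)}",
        )

    # integer species codes, grouped by plot (split by lifeform for india_5m)
    all_species = [s.species for s in visit.stems]
    if not all_species:
        return _missing(visit, estimator, n_draw, reps, seed, 0, "empty stem pool")
    code_of = {sp: i for i, sp in enumerate(dict.fromkeys(all_species))}
    plot_index = {p: i for i, p in enumerate(plot_ids)}
    canopy_by_plot: list[list[int]] = [[] for _ in plot_ids]
    other_by_plot: list[list[int]] = [[] for _ in plot_ids]
    for s in visit.stems:
        target = canopy_by_plot if s.lifeform in CANOPY_LIFEFORMS else other_by_plot
        target[plot_index[s.plot_id]].append(code_of[s.species])
    canopy_arr = [np.asarray(c, dtype=np.int64) for c in canopy_by_plot]
    other_arr = [np.asarray(c, dtype=np.int64) for c in other_by_plot]
    n = len(plot_ids)

    counts = np.zeros(reps, dtype=np.int64)
    for r, rng in enumerate(_rep_generators(seed, reps)):
        if dialect == "india_5m":
            tree_sel = rng.choice(n, size=INDIA_TREE_PLOTS, replace=False)
            other_sel = rng.choice(n, size=INDIA_OTHER_PLOTS, replace=False)
            parts = [canopy_arr[i] for i in tree_sel] + [other_arr[i] for i in other_sel]
        else:
            sel = rng.choice(n, size=n_plots_subset, replace=False)
            parts = [canopy_arr[i] for i in sel] + [other_arr[i] for i in sel]
        codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        if codes.size == 0:
            counts[r] = 0  # empty subset repetition, flagged by the zero
            continue
        counts[r] = _unique_count(codes, rng, n_draw)
    return _summarize(counts, visit, estimator, n_draw, reps, seed, len(all_species))


def harmonized_richness_reference(
    ref_visit: ForestVisit,
    n_draw: int = 100,
    reps: int = 1000,
    seed: int = 0,
) -> RarefactionEstimate:
    """Rarefied richness of a 0.1-ha reference transect plot, with its
    small-stem sampling effort reduced to match focal forests.

    Every repetition includes all stems >= 10 cm DBH from the whole plot,
    plus the stems < 10 cm DBH from one uniformly chosen subplot (the other
    nine subplots' small stems are ignored in that repetition).
    """
    geometry = ref_visit.geometry
    if not geometry.is_reference:
        raise ValidationError(
            f"reference harmonization requires the reference dialect, "
            f"got {ref_visit.dialect!r}"
        )
    pool = pool_stems(ref_visit)
    if not pool:
        return _missing(ref_visit, "sr100_reference", n_draw, reps, seed, 0,
                        "empty stem pool")
    code_of = {sp: i for i, sp in enumerate(dict.fromkeys(pool))}
    large: list[int] = []
    small_by_subplot: dict[int, list[int]] = {i: [] for i in range(1, 11)}
    for s in ref_visit.stems:
        if s.dbh_cm >= geometry.tree_dbh_min_cm:
            large.append(code_of[s.species])
        else:
            if s.subplot_index is None:
                raise ValidationError(
                    f"stem {s.stem_id}: small reference stem without subplot_index"
                )
            small_by_subplot[s.subplot_index].append(code_of[s.species])
    large_arr = np.asarray(large, dtype=np.int64)
    small_arr = {k: np.asarray(v, dtype=np.int64) for k, v in small_by_subplot.items()}

    counts = np.empty(reps, dtype=np.int64)
    for r, rng in enumerate(_rep_generators(seed, reps)):
        chosen = int(rng.integers(1, 11))
        codes = np.concatenate([large_arr, small_arr[chosen]])
        if codes.size == 0:
            counts[r] = 0
            continue
        counts[r] = _unique_count(codes, rng, n_draw)
    return _summarize(counts, ref_visit, "sr100_reference", n_draw, reps, seed,
                      len(pool))


def expected_unique_species(n_species: int, n_draw: int) -> float:
    """Closed-form expected unique count for ``n_species`` equally abundant
    species under an n_draw-stem draw with replacement:
    S * (1 - (1 - 1/S)^n)."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    return n_species * (1.0 - (1.0 - 1.0 / n_species) ** n_draw)
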