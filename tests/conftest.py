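import pytest
from hypothesis import settings

from standcompare import (
    ForestVisit,
    Lifeform,
    LandscapeSpec,
    StemRecord,
    simulate_dataset,
)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_visit(stems, plots=None, dialect="ifri_standard", forest_id="F1",
               visit_year=2010, site_id="F1"):
    """Build a visit from (stem_id, plot_id, species, lifeform, dbh) tuples."""
    records = tuple(
        StemRecord(stem_id=s, plot_id=p, species=sp, lifeform=Lifeform(lf),
                   dbh_cm=d, raw_measure_cm=d, subplot_index=sub)
        for s, p, sp, lf, d, *rest in stems
        for sub in [rest[0] if rest else None]
    )
    if plots is None:
        plots = {p for _, p, *_ in stems} or {"p1"}
    return ForestVisit(forest_id=forest_id, visit_year=visit_year,
                       site_id=site_id, dialect=dialect,
                       plots=frozenset(plots), stems=records)


@pytest.fixture
def one_tree_visit():
    """One standard plot containing exactly one 10 cm tree."""
    return make_visit([("s1", "p1", "cedrela odorata", "tree", 10.0)])


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-forest synthetic study shared across read-only tests."""
    return simulate_dataset(LandscapeSpec(n_forests=30, seed=5))
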