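"""Distances, weighted neighborhoods and z-score standardization."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import standcompare as sc
from standcompare.intercomparison import EARTH_RADIUS_KM


def site(sid, lat=0.0, lon=0.0, elev=0.0):
    return sc.Site(site_id=sid, latitude=lat, longitude=lon, elevation_m=elev)


class TestHaversine:
    def test_identity(self):
        assert sc.haversine_km(12.3, -45.6, 12.3, -45.6) == 0.0

    def test_antipodal_half_circumference(self):
        assert sc.haversine_km(0, 0, 0, 180) == pytest.approx(
            math.pi * EARTH_RADIUS_KM, abs=0.1)

    def test_quarter_circumference_to_pole(self):
        assert sc.haversine_km(0, 0, 90, 0) == pytest.approx(
            math.pi / 2 * EARTH_RADIUS_KM, abs=0.1)

    @given(
        lat1=st.floats(-90, 90), lon1=st.floats(-180, 180),
        lat2=st.floats(-90, 90), lon2=st.floats(-180, 180),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_nonnegative(self, lat1, lon1, lat2, lon2):
        d_ab = sc.haversine_km(lat1, lon1, lat2, lon2)
        d_ba = sc.haversine_km(lat2, lon2, lat1, lon1)
        assert d_ab == pytest.approx(d_ba, abs=1e-9)
        assert 0.0 <= d_ab <= math.pi * EARTH_RADIUS_KM + 1e-6

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sc.haversine_km(91, 0, 0, 0)


class TestTotalDistance:
    def test_colocated_is_zero(self):
        a = site("a", 5, 5, 100)
        assert sc.total_distance(a, a).total == 0.0

    def test_three_four_five_triangle(self):
        # 3 km east on the equator, 4 m elevation difference -> 5 units
        dlon = math.degrees(3.0 / EARTH_RADIUS_KM)
        a = site("a", 0.0, 0.0, 100.0)
        b = site("b", 0.0, dlon, 104.0)
        td = sc.total_distance(a, b)
        assert td.geo_km == pytest.approx(3.0, rel=1e-9)
        assert td.elev_m == 4.0
        assert td.total == pytest.approx(5.0, rel=1e-9)

    def test_elevation_only_hits_cutoff_exactly(self):
        a = site("a", 0, 0, 0.0)
        b = site("b", 0, 0, 1000.0)
        assert sc.total_distance(a, b).total == 1000.0

    def test_total_dominates_components(self, small_dataset):
        sites = list(small_dataset.inventory.sites.values())[:6]
        for x in sites:
            for y in sites:
                td = sc.total_distance(x, y)
                assert td.total >= max(td.geo_km, td.elev_m) - 1e-9

    def test_missing_elevation_policy(self):
        a = site("a", 0, 0, float("nan") if False else 0.0)
        # Site itself rejects NaN; the policy applies to externally built sites
        b = object.__new__(sc.Site)
        object.__setattr__(b, "site_id", "b")
        object.__setattr__(b, "latitude", 0.0)
        object.__setattr__(b, "longitude", 0.0)
        object.__setattr__(b, "elevation_m", float("nan"))
        with pytest.raises(sc.ValidationError):
            sc.total_distance(a, b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            td = sc.total_distance(a, b, missing_elevation="zero")
        assert td.elev_m == 0.0


class TestBuildNeighborhood:
    def candidates(self, values, elevs):
        return [
            (f"n{i}", v, site(f"n{i}", elev=e))
            for i, (v, e) in enumerate(zip(values, elevs))
        ]

    def test_identical_values_give_zero_z(self):
        focal = site("f", elev=0.0)
        cands = self.candidates([7.0, 7.0, 7.0], [10, 20, 30])
        r = sc.build_neighborhood("f", 7.0, focal, cands)
        assert r.z == 0.0 and r.weighted_sd == 0.0

    def test_hand_computed_z(self):
        # neighbors 0 and 2 at equal distances: mean 1, sd 1, focal 2 -> z 1
        focal = site("f", elev=0.0)
        cands = self.candidates([0.0, 2.0], [100, 100])
        r = sc.build_neighborhood("f", 2.0, focal, cands)
        assert r.weighted_mean == pytest.approx(1.0)
        assert r.weighted_sd == pytest.approx(1.0)
        assert r.z == pytest.approx(1.0)

    def test_cutoff_excludes_far_neighbor_inclusive_at_bound(self):
        focal = site("f", elev=0.0)
        cands = self.candidates([1.0, 2.0, 3.0], [500, 1000, 1500])
        r = sc.build_neighborhood("f", 2.0, focal, cands)
        assert r.n_neighbors == 2
        assert {nid for nid, _, _ in r.neighbor_table} == {"n0", "n1"}

    def test_weights_normalized_and_inverse_square(self):
        focal = site("f", elev=0.0)
        cands = self.candidates([1.0, 2.0], [100, 200])
        r = sc.build_neighborhood("f", 1.5, focal, cands)
        weights = {nid: w for nid, _, w in r.neighbor_table}
        assert sum(weights.values()) == pytest.approx(1.0, abs=1e-12)
        assert weights["n0"] / weights["n1"] == pytest.approx(4.0)

    def test_matches_from_scratch_arithmetic_oracle(self):
        rng = np.random.default_rng(17)
        focal = site("f", elev=0.0)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            values = rng.normal(10, 3, k)
            elevs = rng.uniform(50, 900, k)
            r = sc.build_neighborhood(
                "f", 11.0, focal, self.candidates(values, elevs))
            # independent arithmetic: plain python loops
            ws = [1.0 / e**2 for e in elevs]
            tot = sum(ws)
            ws = [w / tot for w in ws]
            mean = sum(w * v for w, v in zip(ws, values))
            var = sum(w * (v - mean) ** 2 for w, v in zip(ws, values))
            sd = math.sqrt(var)
            assert r.weighted_mean == pytest.approx(mean, abs=1e-10)
            assert r.weighted_sd == pytest.approx(sd, abs=1e-10)
            assert r.z == pytest.approx((11.0 - mean) / sd, abs=1e-10)

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.1, 20),
        focal_v=st.floats(-5, 5),
        values=st.lists(st.floats(-5, 5), min_size=2, max_size=6),
    )
    @settings(max_examples=150, deadline=None)
    def test_location_scale_equivariance(self, shift, scale, focal_v, values):
        elevs = [100.0 + 37.0 * i for i in range(len(values))]
        focal = site("f", elev=0.0)
        base = sc.build_neighborhood("f", focal_v, focal,
                                     self.candidates(values, elevs))
        moved = sc.build_neighborhood(
            "f", focal_v * scale + shift, focal,
            self.candidates([v * scale + shift for v in values], elevs))
        if base.is_missing or math.isnan(base.z):
            assert moved.is_missing or math.isnan(moved.z)
        else:
            assert moved.z == pytest.approx(base.z, rel=1e-6, abs=1e-6)

    def test_self_and_colocated_candidates_excluded(self):
        focal = site("f", elev=0.0)
        cands = [("f", 9.0, focal), ("twin", 9.0, site("twin", elev=0.0))] + \
            self.candidates([1.0, 2.0], [100, 200])
        with pytest.warns(UserWarning, match="co-located"):
            r = sc.build_neighborhood("f", 1.5, focal, cands)
        assert {nid for nid, _, _ in r.neighbor_table} == {"n0", "n1"}

    def test_insufficient_neighborhood_reported(self):
        focal = site("f", elev=0.0)
        r = sc.build_neighborhood("f", 1.0, focal,
                                  self.candidates([5.0], [100]))
        assert r.is_missing and "insufficient" in r.missing_reason
        assert math.isnan(r.z)


class TestIntercompareAll:
    def make_table(self, ids, values):
        return pd.DataFrame({"forest_id": ids, "site_id": ids, "value": values})

    def test_two_isolated_clusters_standardize_internally(self):
        sites = {}
        ids, values = [], []
        for c, lat in ((0, 0.0), (1, 60.0)):
            for i in range(4):
                fid = f"c{c}f{i}"
                sites[fid] = site(fid, lat=lat, lon=0.0, elev=10.0 * i)
                ids.append(fid)
                values.append(float(c * 100 + i))
        results = sc.intercompare_all(self.make_table(ids, values), sites)
        for r in results:
            cluster = r.focal_id[:2]
            assert all(nid.startswith(cluster) for nid, _, _ in r.neighbor_table)
            assert r.n_neighbors == 3

    def test_duplicate_forest_ids_rejected(self):
        sites = {"a": site("a"), "b": site("b", elev=10)}
        tbl = self.make_table(["a", "a", "b"], [1.0, 2.0, 3.0])
        with pytest.raises(sc.ValidationError, match="duplicated"):
            sc.intercompare_all(tbl, sites)

    def test_reference_mode_requires_reference_table(self):
        sites = {"a": site("a"), "b": site("b", elev=10)}
        with pytest.raises(sc.ValidationError):
            sc.intercompare_all(self.make_table(["a", "b"], [1.0, 2.0]),
                                sites, mode="reference")

    def test_missing_forests_reported_not_dropped(self):
        sites = {"a": site("a"), "b": site("b", lat=50.0), "c": site("c", lat=50.0, elev=9)}
        results = sc.intercompare_all(self.make_table(["a", "b", "c"], [1., 2., 3.]), sites)
        assert len(results) == 3
        by_id = {r.focal_id: r for r in results}
        assert by_id["a"].is_missing  # isolated forest

    def test_null_landscape_z_scores_standard_normal_ish(self):
        # iid values within clusters: z should be centred with SD near 1
        spec = sc.LandscapeSpec(n_forests=200, n_clusters=2, seed=11,
                                density_gradient_per_deg=0.0,
                                richness_gradient_per_deg=0.0)
        sites, _, _ = sc.generate_landscape(spec)
        rng = np.random.default_rng(3)
        tbl = self.make_table(sorted(sites), rng.normal(10, 2, len(sites)))
        results = sc.intercompare_all(tbl, sites)
        z = np.array([r.z for r in results if not r.is_missing])
        assert z.size >= 150
        assert abs(z.mean()) < 0.15
        assert 0.8 <= z.std() <= 1.3  # inverse-square weighting over-disperses
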