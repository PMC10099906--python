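"""Region assignment, geodesic cell areas and percent-change accounting."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from shapely.geometry import box

from habshift.regional_change import (RegionSet, assign_regions, cell_area,
                                      default_measo_sectors,
                                      percent_area_change,
                                      summarize_ensemble)


def grid(ny=10, nx=36, lat0=-60.0, lon0=-180.0, dlon=10.0):
    lats = np.arange(lat0 + 0.5, lat0 + ny)
    lons = lon0 + dlon * (np.arange(nx) + 0.5)
    return lons, lats


def mask_da(vals, lons, lats):
    return xr.DataArray(np.asarray(vals, dtype=bool),
                        coords={"lat": lats, "lon": lons},
                        dims=("lat", "lon"))


class TestRegionSet:
    def test_overlapping_polygons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RegionSet({"a": box(0, -60, 20, -40), "b": box(10, -60, 30, -40)})

    def test_geojson_round_trip(self, tmp_path):
        rs = default_measo_sectors()
        p = tmp_path / "regions.geojson"
        rs.to_geojson(p)
        back = RegionSet.from_geojson(p)
        assert back.names == rs.names
        for name in rs.names:
            assert back.regions[name].equals(rs.regions[name])


class TestAssignRegions:
    def test_centre_in_exactly_one_polygon(self):
        rs = RegionSet({"west": box(0, -60, 20, -40),
                        "east": box(20, -60, 40, -40)})
        labels = assign_regions(np.array([10.5, 30.5, 50.5]),
                                np.array([-50.5]), rs)
        assert labels.to_numpy().tolist() == [["west", "east", ""]]

    def test_no_cell_double_labelled(self):
        rs = default_measo_sectors()
        lons, lats = grid()
        labels = assign_regions(lons, lats, rs).to_numpy()
        # every labelled cell carries exactly one region name
        assert set(np.unique(labels)) <= set(rs.names) | {""}

    def test_five_sector_meridian_split_counts(self):
        # 10-degree-wide cells over the full circle: counts per sector
        # must match the sector widths (Atlantic 100 deg, Central Indian
        # 50, East Indian 70, West Pacific 80, East Pacific 60)
        rs = default_measo_sectors()
        lons, lats = grid(ny=5)
        labels = assign_regions(lons, lats, rs).to_numpy()
        counts = pd.Series(labels.ravel()).value_counts()
        widths = {"Atlantic": 100, "Central Indian": 50, "East Indian": 70,
                  "West Pacific": 80, "East Pacific": 60}
        for name, width in widths.items():
            assert counts[name] == 5 * width / 10.0


class TestCellArea:
    def test_equator_closed_form(self):
        # R^2 * dlon * (sin(0.5deg) - sin(-0.5deg)), R = 6371 km
        expected = 6371.0 ** 2 * np.radians(1.0) * 2 * np.sin(np.radians(0.5))
        assert cell_area(0.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(12364.1548, abs=1e-3)

    def test_hemispheric_symmetry(self):
        lats = np.array([10.0, 33.3, 60.0, 80.0])
        assert np.allclose(cell_area(lats), cell_area(-lats))

    def test_monotone_decrease_toward_pole(self):
        lats = np.arange(-80.5, 0.0)
        areas = cell_area(lats)
        assert np.all(np.diff(areas) > 0)  # toward equator => larger

    def test_total_sphere_area(self):
        # summing 1-degree cells over the globe recovers 4 pi R^2
        lats = np.arange(-89.5, 90.0)
        total = 360.0 * cell_area(lats).sum()
        assert total == pytest.approx(4 * np.pi * 6371.0 ** 2, rel=1e-12)


class TestPercentAreaChange:
    def two_region_setup(self):
        lons = np.arange(0.5, 20.5)
        lats = np.arange(-60.5, -50.5)
        rs = RegionSet({"west": box(0, -61, 10, -50),
                        "east": box(10, -61, 20, -50)})
        labels = assign_regions(lons, lats, rs)
        return lons, lats, labels

    def test_identical_masks_zero_change_everywhere(self):
        lons, lats, labels = self.two_region_setup()
        rng = np.random.default_rng(0)
        m = mask_da(rng.uniform(size=(10, 20)) > 0.5, lons, lats)
        rec = percent_area_change(m, m, labels)
        assert np.allclose(rec["pct_change"], 0.0)

    def test_halving_one_region_gives_minus_fifty(self):
        lons, lats, labels = self.two_region_setup()
        cur = np.zeros((10, 20), dtype=bool)
        cur[4, 0:4] = True   # 4 equal-area cells in 'west', same latitude
        fut = cur.copy()
        fut[4, 0:2] = False  # remove half of them
        rec = percent_area_change(mask_da(cur, lons, lats),
                                  mask_da(fut, lons, lats), labels)
        west = rec[rec.region == "west"].iloc[0]
        assert west["pct_change"] == pytest.approx(-50.0, abs=1e-12)

    def test_three_region_toy_matches_cellwise_oracle(self):
        # brute-force spreadsheet-style oracle: explicit python loop over
        # cells with cos-latitude-weighted areas
        lons = np.arange(0.5, 30.5)
        lats = np.arange(-65.5, -35.5)
        rs = RegionSet({"a": box(0, -66, 10, -35), "b": box(10, -66, 20, -35),
                        "c": box(20, -66, 30, -35)})
        labels = assign_regions(lons, lats, rs)
        rng = np.random.default_rng(5)
        cur = rng.uniform(size=(30, 30)) > 0.7
        fut = rng.uniform(size=(30, 30)) > 0.6
        rec = percent_area_change(mask_da(cur, lons, lats),
                                  mask_da(fut, lons, lats), labels)
        lab_np = labels.to_numpy()
        for name in ("a", "b", "c"):
            a_cur = a_fut = 0.0
            for i in range(30):
                for j in range(30):
                    if lab_np[i, j] != name:
                        continue
                    area = float(cell_area(lats[i]))
                    a_cur += area * cur[i, j]
                    a_fut += area * fut[i, j]
            expected = 100.0 * (a_fut - a_cur) / a_cur
            got = rec[rec.region == name].iloc[0]
            assert got["current_km2"] == pytest.approx(a_cur, rel=1e-9)
            assert got["pct_change"] == pytest.approx(expected, rel=1e-9)

    def test_region_areas_sum_to_total_mask_area(self):
        lons, lats, labels = self.two_region_setup()
        rng = np.random.default_rng(1)
        cur = rng.uniform(size=(10, 20)) > 0.4
        rec = percent_area_change(mask_da(cur, lons, lats),
                                  mask_da(cur, lons, lats), labels)
        areas = np.broadcast_to(cell_area(lats)[:, None], (10, 20))
        assert rec["current_km2"].sum() == pytest.approx(
            float(areas[cur].sum()), rel=1e-12)

    def test_scale_free_under_area_rescaling(self):
        lons, lats, labels = self.two_region_setup()
        rng = np.random.default_rng(2)
        cur = mask_da(rng.uniform(size=(10, 20)) > 0.5, lons, lats)
        fut = mask_da(rng.uniform(size=(10, 20)) > 0.5, lons, lats)
        areas = xr.DataArray(
            np.broadcast_to(cell_area(lats)[:, None], (10, 20)).copy(),
            coords=cur.coords, dims=cur.dims)
        r1 = percent_area_change(cur, fut, labels, cell_areas=areas)
        r2 = percent_area_change(cur, fut, labels, cell_areas=areas * 7.5)
        assert np.allclose(r1["pct_change"], r2["pct_change"], equal_nan=True)

    def test_zero_current_flagged(self):
        lons, lats, labels = self.two_region_setup()
        cur = np.zeros((10, 20), dtype=bool)
        fut = np.zeros((10, 20), dtype=bool)
        fut[0, 15] = True
        rec = percent_area_change(mask_da(cur, lons, lats),
                                  mask_da(fut, lons, lats), labels)
        east = rec[rec.region == "east"].iloc[0]
        assert east["zero_current"]
        assert np.isnan(east["pct_change"])

    def test_grid_mismatch_rejected(self):
        lons, lats, labels = self.two_region_setup()
        m1 = mask_da(np.zeros((10, 20)), lons, lats)
        m2 = mask_da(np.zeros((5, 20)), lons, lats[:5])
        with pytest.raises(ValueError, match="grid"):
            percent_area_change(m1, m2, labels)


class TestSummarizeEnsemble:
    def records(self, values, region="a", scenario="s"):
        return pd.DataFrame({
            "taxon": "t", "region": region, "scenario": scenario,
            "representation": [f"r{i}" for i in range(len(values))],
            "pct_change": values,
        })

    def test_identical_records_collapse(self):
        s = summarize_ensemble(self.records([3.2] * 8))
        row = s.iloc[0]
        assert row["median"] == row["q25"] == row["q75"] == 3.2
        assert row["min"] == row["max"] == 3.2

    def test_quartiles_linear_interpolation(self):
        # frozen oracle: np.percentile([-4,-2,0,2], [25,50,75])
        s = summarize_ensemble(self.records([-4.0, -2.0, 0.0, 2.0])).iloc[0]
        assert s["median"] == pytest.approx(-1.0)
        assert s["q25"] == pytest.approx(-2.5)
        assert s["q75"] == pytest.approx(0.5)

    def test_order_invariance(self):
        vals = [5.0, -3.0, 1.5, 0.0, 9.9]
        s1 = summarize_ensemble(self.records(vals))
        s2 = summarize_ensemble(self.records(vals[::-1]))
        pd.testing.assert_frame_equal(
            s1.drop(columns="n"), s2.drop(columns="n"))
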