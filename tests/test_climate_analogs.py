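"""Normalise -> PCA -> k-NN analogue classification and ensembling."""

import numpy as np
import pytest
import xarray as xr

from habshift.climate_analogs import (CATEGORY_CODES, AnalogueProjection,
                                      ClimateRepresentation,
                                      ensemble_combine, knn_analog_classify,
                                      normalize_variables, reduce_dimensions)
from tests.conftest import make_stack


def pair_of_stacks(cur_vals: dict, fut_vals: dict):
    return make_stack(cur_vals), make_stack(fut_vals)


class TestNormalize:
    def test_affine_map_and_exact_bounds(self):
        cur, fut = pair_of_stacks(
            {"sst": np.array([[-2.0, 0.0], [1.0, 2.0]])},
            {"sst": np.array([[0.0, 1.0], [2.0, -1.0]])})
        c, f, scaling, dropped = normalize_variables(cur, fut, ("sst",))
        assert scaling["sst"] == (-2.0, 2.0)
        assert c["sst"].to_numpy()[0, 0] == 0.0
        assert c["sst"].to_numpy()[1, 1] == 1.0
        assert c["sst"].to_numpy()[0, 1] == pytest.approx(0.5)
        assert not dropped
        # pooled scale: both periods normalised with one min/max
        assert f["sst"].to_numpy()[1, 1] == pytest.approx(0.25)

    def test_idempotent_on_unit_interval(self):
        rng = np.random.default_rng(0)
        cur, fut = pair_of_stacks({"sst": rng.uniform(0, 1, (4, 5))},
                                  {"sst": rng.uniform(0, 1, (4, 5))})
        c1, f1, _, _ = normalize_variables(cur, fut, ("sst",))
        from habshift.env_match import EnvStack
        c2, f2, _, _ = normalize_variables(EnvStack(c1), EnvStack(f1), ("sst",))
        # pooled bounds of normalised data are exactly [0, 1], so a second
        # pass is the identity
        assert np.allclose(c2["sst"].to_numpy(), c1["sst"].to_numpy())
        assert np.allclose(f2["sst"].to_numpy(), f1["sst"].to_numpy())

    def test_constant_variable_dropped(self):
        cur, fut = pair_of_stacks(
            {"sst": np.ones((3, 3)), "bathymetry": np.arange(9.0).reshape(3, 3)},
            {"sst": np.ones((3, 3)), "bathymetry": np.arange(9.0).reshape(3, 3)})
        c, f, scaling, dropped = normalize_variables(
            cur, fut, ("sst", "bathymetry"))
        assert dropped == ["sst"]
        assert "bathymetry" in scaling

    def test_all_constant_rejected(self):
        cur, fut = pair_of_stacks({"sst": np.ones((2, 2))},
                                  {"sst": np.ones((2, 2))})
        with pytest.raises(ValueError, match="no scalable"):
            normalize_variables(cur, fut, ("sst",))


class TestReduceDimensions:
    def test_single_variable_one_component(self):
        rng = np.random.default_rng(1)
        cur, fut = pair_of_stacks({"sst": rng.uniform(0, 1, (5, 6))},
                                  {"sst": rng.uniform(0, 1, (5, 6))})
        c, f, _, _ = normalize_variables(cur, fut, ("sst",))
        _, _, _, n_comp, var = reduce_dimensions(c, f)
        assert n_comp == 1
        assert var == pytest.approx(1.0)

    def test_collinear_pair_one_component(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, (5, 6))
        cur, fut = pair_of_stacks({"sst": x, "sea_surface_height": 2 * x},
                                  {"sst": x, "sea_surface_height": 2 * x})
        c, f, _, _ = normalize_variables(cur, fut,
                                         ("sst", "sea_surface_height"))
        _, _, _, n_comp, _ = reduce_dimensions(c, f)
        assert n_comp == 1

    def test_independent_equal_variance_pair_two_components(self):
        rng = np.random.default_rng(3)
        cur, fut = pair_of_stacks(
            {"sst": rng.uniform(0, 1, (40, 50)),
             "sea_surface_height": rng.uniform(0, 1, (40, 50))},
            {"sst": rng.uniform(0, 1, (40, 50)),
             "sea_surface_height": rng.uniform(0, 1, (40, 50))})
        c, f, _, _ = normalize_variables(cur, fut,
                                         ("sst", "sea_surface_height"))
        _, _, _, n_comp, _ = reduce_dimensions(c, f)
        assert n_comp == 2  # each component explains ~50% < 95%


def brute_force_knn(cur_feat, labels, fut_feat, k):
    """Independent oracle: exhaustive distances, stable tie-break by
    ascending current-cell index, majority vote."""
    out = []
    for x in fut_feat:
        d = np.sqrt(((cur_feat - x) ** 2).sum(axis=1))
        order = sorted(range(len(d)), key=lambda i: (d[i], i))[:k]
        out.append(sum(labels[i] for i in order) * 2 > k)
    return np.array(out, dtype=bool)


class TestKnnClassify:
    def mask_da(self, vals):
        vals = np.asarray(vals, dtype=bool)
        ny, nx = vals.shape
        return xr.DataArray(vals,
                            coords={"lat": np.arange(-60.5, -60.5 + ny),
                                    "lon": np.arange(0.5, 0.5 + nx)},
                            dims=("lat", "lon"))

    def test_identity_projection_k1(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 10, (6, 8))
        cur, fut = pair_of_stacks({"sst": vals}, {"sst": vals.copy()})
        rep = ClimateRepresentation("r1", "syn", ("sst",), cur, fut)
        mask = self.mask_da(vals > 7.0)
        proj = knn_analog_classify(rep, mask, k=1)
        assert np.array_equal(proj.layer.to_numpy(), mask.to_numpy())

    def test_six_cell_toy_by_enumeration(self):
        # 3 preferred cells at {0.0, 0.1, 0.2}, 3 not at {0.8, 0.9, 1.0};
        # a future cell at 0.15 with k=3 takes neighbours {0.1, 0.2, 0.0}
        # => preferred-like (checked against brute-force enumeration)
        cur_vals = np.array([[0.0, 0.1, 0.2, 0.8, 0.9, 1.0]])
        fut_vals = np.array([[0.15, 0.15, 0.15, 0.15, 0.15, 0.15]])
        cur, fut = pair_of_stacks({"sst": cur_vals}, {"sst": fut_vals})
        rep = ClimateRepresentation("toy", "syn", ("sst",), cur, fut)
        mask = self.mask_da([[True, True, True, False, False, False]])
        proj = knn_analog_classify(rep, mask, k=3)
        assert proj.layer.to_numpy().all()
        oracle = brute_force_knn(cur_vals.reshape(-1, 1),
                                 mask.to_numpy().ravel(),
                                 fut_vals.reshape(-1, 1), k=3)
        assert np.array_equal(proj.layer.to_numpy().ravel(), oracle)

    def test_unanimous_labels_propagate(self):
        rng = np.random.default_rng(5)
        cur, fut = pair_of_stacks({"sst": rng.uniform(0, 1, (4, 5))},
                                  {"sst": rng.uniform(0, 1, (4, 5))})
        rep = ClimateRepresentation("r", "syn", ("sst",), cur, fut)
        mask = self.mask_da(np.ones((4, 5)))
        proj = knn_analog_classify(rep, mask, k=5)
        assert proj.layer.to_numpy().all()

    def test_k_larger_than_cells_rejected(self):
        rng = np.random.default_rng(6)
        cur, fut = pair_of_stacks({"sst": rng.uniform(0, 1, (2, 2))},
                                  {"sst": rng.uniform(0, 1, (2, 2))})
        rep = ClimateRepresentation("r", "syn", ("sst",), cur, fut)
        with pytest.raises(ValueError, match="k="):
            knn_analog_classify(rep, self.mask_da(np.eye(2)), k=9)

    def test_matches_brute_force_on_random_problems(self):
        # multivariate random problems, including accessibility as the
        # extra feature dimension
        rng = np.random.default_rng(7)
        for trial in range(5):
            ny, nx = rng.integers(3, 8), rng.integers(3, 8)
            cur_vals = {"sst": rng.uniform(0, 1, (ny, nx)),
                        "sea_surface_height": rng.uniform(0, 1, (ny, nx))}
            fut_vals = {"sst": rng.uniform(0, 1, (ny, nx)),
                        "sea_surface_height": rng.uniform(0, 1, (ny, nx))}
            cur, fut = pair_of_stacks(cur_vals, fut_vals)
            rep = ClimateRepresentation(f"r{trial}", "syn",
                                        ("sst", "sea_surface_height"),
                                        cur, fut)
            mask = self.mask_da(rng.uniform(size=(ny, nx)) > 0.6)
            access = xr.DataArray(rng.uniform(0, 1, (ny, nx)),
                                  coords=mask.coords, dims=mask.dims)
            proj = knn_analog_classify(rep, mask, accessibility=access, k=3)
            # rebuild the embedded features exactly as the implementation
            c, f, _, _ = normalize_variables(cur, fut,
                                             ("sst", "sea_surface_height"))
            sc, sf, ok, n_comp, _ = reduce_dimensions(c, f)
            a = access.to_numpy().ravel()[ok][:, None]
            oracle = brute_force_knn(np.hstack([sc, a]),
                                     mask.to_numpy().ravel()[ok],
                                     np.hstack([sf, a]), k=3)
            assert np.array_equal(proj.layer.to_numpy().ravel()[ok], oracle)


class TestEnsemble:
    def proj(self, vals, name="r", scenario="syn"):
        vals = np.asarray(vals, dtype=bool)
        ny, nx = vals.shape
        layer = xr.DataArray(vals,
                             coords={"lat": np.arange(-60.5, -60.5 + ny),
                                     "lon": np.arange(0.5, 0.5 + nx)},
                             dims=("lat", "lon"))
        return AnalogueProjection(name, scenario, layer, 5, 1, 1.0)

    def test_identical_projections_combine_to_one(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(size=(5, 6)) > 0.5
        projs = [self.proj(vals, name=f"r{i}") for i in range(8)]
        cur = self.proj(rng.uniform(size=(5, 6)) > 0.5).layer
        out = ensemble_combine(projs, cur)
        assert np.array_equal(out["future_preferred"].to_numpy(), vals)
        assert np.all(out["agreement"].to_numpy()[vals] == 8)

    def test_majority_five_of_eight(self):
        yes, no = np.ones((1, 1)), np.zeros((1, 1))
        projs = ([self.proj(yes, name=f"y{i}") for i in range(5)]
                 + [self.proj(no, name=f"n{i}") for i in range(3)])
        cur = self.proj(no).layer
        out = ensemble_combine(projs, cur)
        assert bool(out["future_preferred"].item())
        assert int(out["agreement"].item()) == 5
        assert int(out["category"].item()) == CATEGORY_CODES["gained"]

    def test_tie_is_not_preferred(self):
        yes, no = np.ones((1, 1)), np.zeros((1, 1))
        projs = ([self.proj(yes, name=f"y{i}") for i in range(4)]
                 + [self.proj(no, name=f"n{i}") for i in range(4)])
        out = ensemble_combine(projs, self.proj(yes).layer)
        assert not bool(out["future_preferred"].item())
        assert int(out["category"].item()) == CATEGORY_CODES["lost"]

    def test_categories_partition_every_cell(self):
        rng = np.random.default_rng(9)
        projs = [self.proj(rng.uniform(size=(6, 7)) > 0.5, name=f"r{i}")
                 for i in range(5)]
        cur = self.proj(rng.uniform(size=(6, 7)) > 0.5).layer
        out = ensemble_combine(projs, cur)
        cat = out["category"].to_numpy()
        assert set(np.unique(cat)) <= set(CATEGORY_CODES.values())
        retained = cat == CATEGORY_CODES["retained"]
        lost = cat == CATEGORY_CODES["lost"]
        gained = cat == CATEGORY_CODES["gained"]
        never = cat == CATEGORY_CODES["never"]
        assert np.all(retained + lost + gained + never == 1)
        cur_np = cur.to_numpy()
        fut_np = out["future_preferred"].to_numpy()
        assert np.array_equal(retained, cur_np & fut_np)
        assert np.array_equal(gained, ~cur_np & fut_np)

    def test_mixed_scenarios_rejected(self):
        a = self.proj(np.ones((2, 2)), scenario="rcp45")
        b = self.proj(np.ones((2, 2)), scenario="rcp85")
        with pytest.raises(ValueError, match="scenario"):
            ensemble_combine([a, b], a.layer)
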