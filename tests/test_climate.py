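import numpy as np
import pandas as pd
import pytest

from habscape import climate as cl
from habscape.grids import Grid, Raster, RasterStack
from habscape.occurrences import SampleTable

from .conftest import separable_table, table_from_arrays


class TestBuildFeatures:
    def test_linear_only_count(self):
        spec = cl.FeatureSpec(("linear",))
        X = np.random.default_rng(0).random((20, 3))
        F, names = cl.build_features(X, ["a", "b", "c"], spec, fit_normalization=True)
        assert F.shape == (20, 3)

    def test_quadratic_on_binary_is_identity(self):
        spec = cl.FeatureSpec(("linear", "quadratic"))
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        F, names = cl.build_features(X, ["x"], spec, fit_normalization=True)
        assert np.allclose(F[:, 0], F[:, 1])  # x^2 == x on {0,1}

    def test_hinge_column_count(self):
        spec = cl.FeatureSpec(("hinge",), hinge_knots=3)
        X = np.random.default_rng(1).random((30, 1))
        F, names = cl.build_features(X, ["x"], spec, fit_normalization=True)
        assert F.shape[1] == 6  # both orientations per knot

    def test_constant_covariate_dropped(self):
        spec = cl.FeatureSpec(("linear",))
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="constant"):
            F, names = cl.build_features(X, ["c", "x"], spec, fit_normalization=True)
        assert names == ["x"]

    def test_bad_class(self):
        with pytest.raises(ValueError):
            cl.FeatureSpec(("cubic",))


class TestFitMaxent:
    def test_null_data_shrinks_coefficients(self):
        rng = np.random.default_rng(0)
        X = rng.random((2000, 2))
        y = np.repeat([1, 0], 1000)
        table = table_from_arrays(X, y, ["a", "b"])
        model = cl.fit_maxent(table, reg_multiplier=1.0)
        assert np.all(np.abs(model.coefficients) < 0.05)

    def test_sign_recovery(self):
        model = cl.fit_maxent(
            separable_table(), reg_multiplier=0.5, spec=cl.FeatureSpec(("linear",))
        )
        linear = model.coefficients[model.feature_names.index("x")]
        assert linear > 0

    def test_penalty_monotonicity_on_grid(self):
        table = separable_table(n=150, seed=3)
        ks = [cl.fit_maxent(table, m).n_nonzero for m in cl.DEFAULT_REG_GRID]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_too_few_points(self):
        table = separable_table(n=5)
        with pytest.raises(ValueError):
            cl.fit_maxent(table)

    def test_predictions_bounded(self):
        model = cl.fit_maxent(separable_table())
        p = model.predict(np.linspace(-1, 2, 50)[:, None])
        assert (p >= 0).all() and (p <= 1).all()

    def test_serialization_roundtrip(self):
        model = cl.fit_maxent(separable_table())
        back = cl.MaxentModel.from_json(model.to_json())
        X = np.random.default_rng(5).random((20, 1))
        assert np.allclose(model.predict(X), back.predict(X))


class TestSweep:
    def test_default_grid_six_candidates(self):
        sweep = cl.sweep_regularization(separable_table())
        assert len(sweep.candidates) == 6
        assert [c["reg_multiplier"] for c in sweep.candidates] == list(cl.DEFAULT_REG_GRID)

    def test_single_multiplier(self):
        sweep = cl.sweep_regularization(separable_table(), multipliers=[1.5])
        assert sweep.selected == 0
        assert sweep.model.reg_multiplier == 1.5

    def test_aic_arithmetic_oracle(self):
        sweep = cl.sweep_regularization(separable_table())
        for c in sweep.candidates:
            assert c["aic"] == pytest.approx(2 * c["k"] - 2 * c["log_likelihood"])

    def test_selection_is_argmin(self):
        sweep = cl.sweep_regularization(separable_table())
        aics = [c["aic"] for c in sweep.candidates]
        assert sweep.candidates[sweep.selected]["aic"] == min(aics)

    def test_order_invariance(self):
        table = separable_table(seed=9)
        fwd = cl.sweep_regularization(table, multipliers=list(cl.DEFAULT_REG_GRID))
        rev = cl.sweep_regularization(table, multipliers=list(cl.DEFAULT_REG_GRID)[::-1])
        assert (
            fwd.candidates[fwd.selected]["reg_multiplier"]
            == rev.candidates[rev.selected]["reg_multiplier"]
        )

    def test_empty_grid(self):
        with pytest.raises(ValueError):
            cl.sweep_regularization(separable_table(), multipliers=[])


class TestCheckerboard:
    def test_parity_on_4x4(self):
        g = Grid(4, 4, 1.0)
        rows, cols = np.mgrid[0:4, 0:4]
        x, y = g.cell_center(rows.ravel(), cols.ravel())
        pts = pd.DataFrame({"lon": x, "lat": y})
        folds = cl.checkerboard_partition(pts, g, aggregation_factor=2)
        expected = ((rows.ravel() // 2 + cols.ravel() // 2) % 2).astype(int)
        assert np.array_equal(folds, expected)

    def test_single_block_warns(self):
        g = Grid(4, 4, 1.0)
        pts = pd.DataFrame({"lon": [0.5, 0.6], "lat": [-0.5, -0.6]})
        with pytest.warns(UserWarning, match="single"):
            cl.checkerboard_partition(pts, g, aggregation_factor=4)

    def test_balanced_on_uniform_points(self):
        g = Grid(100, 100, 1.0)
        rng = np.random.default_rng(0)
        pts = pd.DataFrame({"lon": rng.uniform(0, 100, 2000), "lat": -rng.uniform(0, 100, 2000)})
        folds = cl.checkerboard_partition(pts, g, aggregation_factor=5)
        assert abs(folds.mean() - 0.5) < 0.05

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            cl.checkerboard_partition(pd.DataFrame({"lon": [0], "lat": [0]}), Grid(4, 4, 1.0), 0)


class TestCvEvaluate:
    def test_separable_auc_1(self):
        table = separable_table(n=100)
        folds = np.tile([0, 1], len(table.data) // 2)
        aucs = cl.cv_evaluate(table, folds)
        assert all(a == 1.0 for a in aucs)
        assert len(aucs) == 2

    def test_shuffled_labels_null(self):
        rng = np.random.default_rng(4)
        X = rng.random((1000, 2))
        y = rng.permutation(np.repeat([0, 1], 500))
        table = table_from_arrays(X, y, ["a", "b"])
        folds = np.tile([0, 1], 500)
        aucs = cl.cv_evaluate(table, folds)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_fold_raises(self):
        with pytest.raises(ValueError):
            cl.cv_evaluate(separable_table(), np.zeros(400))


def toy_model_and_stack():
    table = separable_table(n=100, seed=2)
    model = cl.fit_maxent(table, reg_multiplier=0.5)
    g = Grid(5, 5, 1.0)
    stack = RasterStack({"x": Raster(g, np.linspace(0, 1, 25).reshape(5, 5))})
    return model, stack


class TestPredictSurface:
    def test_constant_stack(self):
        model, _ = toy_model_and_stack()
        g = Grid(3, 3, 1.0)
        stack = RasterStack({"x": Raster(g, np.full((3, 3), 0.8))})
        surf = cl.predict_surface(model, stack)
        expected = model.predict(np.array([[0.8]]))[0]
        assert np.allclose(surf.values, expected)

    def test_bounds_and_monotone(self):
        model, stack = toy_model_and_stack()
        surf = cl.predict_surface(model, stack)
        v = surf.values.ravel()
        assert (v >= 0).all() and (v <= 1).all()
        assert (np.diff(v) >= -1e-12).all()  # positive effect of x

    def test_clamping_flagged(self):
        model, _ = toy_model_and_stack()
        g = Grid(2, 2, 1.0)
        stack = RasterStack({"x": Raster(g, np.array([[5.0, 0.5], [0.5, 0.5]]))})
        surf = cl.predict_surface(model, stack)
        assert model.n_clamped == 1
        inmax = model.predict(np.array([[1.0]]))[0]
        assert surf.values[0, 0] == pytest.approx(inmax)

    def test_dot_product_oracle(self):
        model, stack = toy_model_and_stack()
        surf = cl.predict_surface(model, stack)
        x = stack["x"].values[2, 2]
        lo, hi = model.spec.normalization["x"]
        z = np.clip((x - lo) / (hi - lo), 0, 1)
        feats = [z]
        if "quadratic" in model.spec.classes:
            feats.append(z**2)
        eta = np.dot(model.coefficients, feats) + model.intercept
        assert surf.values[2, 2] == pytest.approx(1 / (1 + np.exp(-eta)))

    def test_missing_layer(self):
        model, _ = toy_model_and_stack()
        g = Grid(2, 2, 1.0)
        with pytest.raises(KeyError):
            cl.predict_surface(model, RasterStack({"y": Raster(g, np.zeros((2, 2)))}))

    def test_nodata_propagates(self):
        model, stack = toy_model_and_stack()
        v = stack["x"].values.copy()
        v[0, 0] = np.nan
        surf = cl.predict_surface(model, RasterStack({"x": Raster(stack.grid, v)}))
        assert np.isnan(surf.values[0, 0])


class TestProjectGcms:
    def test_identical_stacks(self):
        model, stack = toy_model_and_stack()
        single = cl.predict_surface(model, stack)
        mean, bsum = cl.project_gcms(model, [stack, stack, stack], threshold=0.5)
        assert np.allclose(mean.values, single.values)
        assert set(np.unique(bsum.values)) <= {0.0, 3.0}

    def test_order_invariance(self):
        model, stack = toy_model_and_stack()
        g = stack.grid
        s2 = RasterStack({"x": Raster(g, stack["x"].values[::-1].copy())})
        m1, b1 = cl.project_gcms(model, [stack, s2], 0.5)
        m2, b2 = cl.project_gcms(model, [s2, stack], 0.5)
        assert np.array_equal(m1.values, m2.values)
        assert np.array_equal(b1.values, b2.values)

    def test_arithmetic(self):
        # three stacks engineered to predict approximately {p1,p2,p3} at a cell
        model, stack = toy_model_and_stack()
        preds = [cl.predict_surface(model, stack).values for _ in range(3)]
        mean, bsum = cl.project_gcms(model, [stack] * 3, threshold=0.5)
        assert np.allclose(mean.values, np.mean(preds, axis=0))
        assert np.allclose(bsum.values, 3 * (preds[0] >= 0.5))

    def test_bad_threshold(self):
        model, stack = toy_model_and_stack()
        with pytest.raises(ValueError):
            cl.project_gcms(model, [stack], 1.5)

    def test_no_stacks(self):
        model, _ = toy_model_and_stack()
        with pytest.raises(ValueError):
            cl.project_gcms(model, [], 0.5)


class TestMop:
    def make_projection(self, values):
        arr = np.asarray(values, dtype=float)
        g = Grid(arr.shape[0], arr.shape[1], 1.0)
        return RasterStack({"x": Raster(g, arr)})

    def test_similarity_1_on_calibration_point(self):
        # fraction 0.1 of 10 rows -> nearest single row; zero distance at a
        # cell that coincides with a calibration row
        calib = np.arange(10.0)[:, None]
        proj = self.make_projection([[5.0, 20.0]])
        out = cl.mop(calib, proj, ["x"], fraction=0.1)
        assert out.similarity.values[0, 0] == pytest.approx(1.0)

    def test_extrapolation_flag(self):
        calib = np.arange(10.0)[:, None]
        proj = self.make_projection([[5.0, 25.0]])
        out = cl.mop(calib, proj, ["x"], fraction=0.5)
        assert out.extrapolation_mask.values[0, 0] == 0
        assert out.extrapolation_mask.values[0, 1] == 1

    def test_1d_bruteforce_oracle(self):
        calib = np.array([0.0, 1.0, 2.0] * 4)[:, None]  # 12 rows
        proj = self.make_projection([[4.0, 1.0]])
        out = cl.mop(calib, proj, ["x"], fraction=1.0)
        mu, sd = calib.mean(), calib.std()
        z = (np.array([4.0, 1.0]) - mu) / sd
        cz = (calib.ravel() - mu) / sd
        d = [np.abs(cz - v).mean() for v in z]
        sims = 1 - np.array(d) / max(d)
        assert np.allclose(out.similarity.values[0], sims)

    def test_monotone_decay_1d(self):
        rng = np.random.default_rng(0)
        calib = rng.normal(0, 1, 200)[:, None]
        cells = np.linspace(0, 6, 10)[None, :]
        out = cl.mop(calib, self.make_projection(cells), ["x"], fraction=0.1)
        sims = out.similarity.values[0]
        assert (np.diff(sims) <= 1e-12).all()

    def test_range_and_errors(self):
        calib = np.arange(20.0)[:, None]
        out = cl.mop(calib, self.make_projection([[3.0, 30.0]]), ["x"])
        v = out.similarity.values
        assert np.nanmin(v) >= 0 and np.nanmax(v) <= 1
        with pytest.raises(ValueError):
            cl.mop(calib, self.make_projection([[1.0]]), ["x"], fraction=0.0)
        with pytest.raises(ValueError):
            cl.mop(np.arange(5.0)[:, None], self.make_projection([[1.0]]), ["x"])


class TestNicheRecovery:
    def test_spearman_against_truth(self, pack, covariates, suitability):
        # fitted ranking should correlate with the generating surface
        from scipy.stats import spearmanr

        from habscape import synth
        from habscape.occurrences import extract_covariates, sample_background

        occ = synth.sample_occurrences(suitability, 1000, 11)
        bg = sample_background(occ, pack.grid, seed=12, buffer_km=5.0)
        names = ["frac_grass", "frac_shrub", "frac_barren"]
        sub = covariates.subset(names)
        pres = extract_covariates(occ, sub, "presence")
        back = extract_covariates(bg, sub, "background")
        table = SampleTable(
            pd.concat([pres.data, back.data], ignore_index=True), pres.covariate_names
        )
        sweep = cl.sweep_regularization(table)
        surf = cl.predict_surface(sweep.model, sub)
        rho = spearmanr(surf.values.ravel(), suitability.values.ravel()).statistic
        assert rho > 0.6
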