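import numpy as np
import pandas as pd
import pytest

from habscape import ssf, synth
from habscape.grids import Grid, Raster, RasterStack


def make_track(n, rate_h=4.0, individual="a", start=(50.0, -50.0), seed=0):
    rng = np.random.default_rng(seed)
    steps = rng.normal(0, 2.0, (n - 1, 2))
    xy = np.vstack([start, start + np.cumsum(steps, axis=0)])
    t = pd.Timestamp("2020-01-01") + pd.to_timedelta(np.arange(n) * rate_h, unit="h")
    return pd.DataFrame({"individual": individual, "timestamp": t, "lon": xy[:, 0], "lat": xy[:, 1]})


class TestMakeSteps:
    def test_min_points_filter(self):
        tracks = pd.concat([make_track(99, individual="short"), make_track(120, individual="long")])
        steps = ssf.make_steps(tracks, min_points=100)
        assert set(steps.data["individual"]) == {"long"}

    def test_allowed_rate_kept(self):
        steps = ssf.make_steps(make_track(120, rate_h=4.0), min_points=100)
        assert steps.n_cases() == 119

    def test_disallowed_rate_dropped(self):
        with pytest.raises(ValueError):
            ssf.make_steps(make_track(120, rate_h=7.0), min_points=100)

    def test_nonuniform_rate_dropped(self):
        tr = make_track(120, rate_h=4.0)
        jitter = pd.to_timedelta(np.random.default_rng(0).uniform(0, 3, 120), unit="h")
        tr["timestamp"] = tr["timestamp"] + jitter
        with pytest.raises(ValueError):
            ssf.make_steps(tr, min_points=100)

    def test_collinear_turn_angle_zero(self):
        t = pd.Timestamp("2020-01-01") + pd.to_timedelta([0, 4, 8], unit="h")
        tr = pd.DataFrame(
            {"individual": "a", "timestamp": t, "lon": [0.0, 1.0, 2.0], "lat": [0.0, 1.0, 2.0]}
        )
        steps = ssf.make_steps(tr, min_points=3)
        assert steps.data["turn_angle"].iloc[1] == pytest.approx(0.0)

    def test_one_case_per_stratum(self):
        steps = ssf.make_steps(make_track(150), min_points=100)
        assert steps.data.groupby("stratum")["case"].sum().eq(1).all()


class TestFitStepDistributions:
    def test_gamma_recovery(self):
        rng = np.random.default_rng(1)
        lengths = rng.gamma(2.0, 100.0, 2000)
        turns = rng.vonmises(0.0, 2.0, 2000)
        d = ssf.fit_step_distributions(lengths, turns)
        assert 1.8 <= d.gamma_shape <= 2.2

    def test_uniform_turns_kappa_zero(self):
        rng = np.random.default_rng(2)
        d = ssf.fit_step_distributions(rng.gamma(2, 100, 2000), rng.uniform(-np.pi, np.pi, 2000))
        assert d.kappa < 0.1

    def test_degenerate_lengths(self):
        with pytest.raises(ValueError, match="degenerate"):
            ssf.fit_step_distributions(np.full(100, 5.0), np.zeros(100))

    def test_too_few(self):
        with pytest.raises(ValueError):
            ssf.fit_step_distributions(np.arange(10.0), np.zeros(10))


class TestGenerateRandomSteps:
    def setup_steps(self, n=10):
        grid = Grid(200, 200, 1.0, origin_x=-100.0, origin_y=100.0)
        tr = make_track(n + 1, individual="a", start=(0.0, -0.0), seed=3)
        steps = ssf.make_steps(tr, min_points=3)
        dists = {"a": ssf.StepDistributions(2.0, 1.0, 0.5)}
        return grid, steps, dists

    def test_row_count(self):
        grid, steps, dists = self.setup_steps(10)
        aug = ssf.generate_random_steps(steps, dists, grid, k=15, seed=0)
        assert len(aug.data) == 10 * 16
        assert aug.data["stratum"].nunique() == 10

    def test_k_zero_identity(self):
        grid, steps, dists = self.setup_steps(5)
        aug = ssf.generate_random_steps(steps, dists, grid, k=0, seed=0)
        assert len(aug.data) == len(steps.data)

    def test_reproducible(self):
        grid, steps, dists = self.setup_steps(8)
        a = ssf.generate_random_steps(steps, dists, grid, k=15, seed=9)
        b = ssf.generate_random_steps(steps, dists, grid, k=15, seed=9)
        assert a.data.equals(b.data)

    def test_controls_share_start(self):
        grid, steps, dists = self.setup_steps(6)
        aug = ssf.generate_random_steps(steps, dists, grid, k=5, seed=1)
        for _, grp in aug.data.groupby("stratum"):
            assert grp["x_start"].nunique() == 1
            assert grp["case"].sum() == 1

    def test_missing_dists(self):
        grid, steps, _ = self.setup_steps(5)
        with pytest.raises(KeyError):
            ssf.generate_random_steps(steps, {}, grid, k=5, seed=0)


def tiny_stepset(n_strata=4, k=3, p=2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_strata):
        for j in range(k + 1):
            rows.append({"stratum": s, "case": j == 0, "individual": "a",
                         **{f"c{i}": rng.normal() for i in range(p)}})
    return ssf.StepSet(pd.DataFrame(rows), [f"c{i}" for i in range(p)])


class TestFitClogit:
    def test_constant_within_strata_dropped(self):
        ss = tiny_stepset(5, 3, 1)
        ss.data["const"] = ss.data["stratum"].astype(float)  # varies only across strata
        ss.covariate_names = ["c0", "const"]
        with pytest.warns(UserWarning, match="constant within strata"):
            fit = ssf.fit_clogit(ss)
        assert fit.beta[1] == 0.0
        assert "const" in fit.dropped_covariates

    def test_mirrored_strata_beta_zero(self):
        rows = []
        for s, sign in [(0, 1.0), (1, -1.0)]:
            rows.append({"stratum": s, "case": True, "individual": "a", "x": sign})
            rows.append({"stratum": s, "case": False, "individual": "a", "x": -sign})
        fit = ssf.fit_clogit(ssf.StepSet(pd.DataFrame(rows), ["x"]))
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_partial_likelihood_matches_oracle(self):
        ss = tiny_stepset(5, 3, 2, seed=4)
        fit = ssf.fit_clogit(ss)
        X = ss.data[ss.covariate_names].to_numpy()
        oracle = ssf.clogit_loglik(
            X, ss.data["case"].to_numpy(), ss.data["stratum"].to_numpy(), fit.beta
        )
        assert fit.log_partial_likelihood == pytest.approx(oracle, abs=1e-9)

    def test_fit_beats_grid_oracle(self):
        ss = tiny_stepset(5, 3, 1, seed=5)
        fit = ssf.fit_clogit(ss)
        X = ss.data[ss.covariate_names].to_numpy()
        case = ss.data["case"].to_numpy()
        strata = ss.data["stratum"].to_numpy()
        grid_ll = max(
            ssf.clogit_loglik(X, case, strata, np.array([b])) for b in np.linspace(-5, 5, 2001)
        )
        assert fit.log_partial_likelihood >= grid_ll - 1e-6

    def test_separation_detected(self):
        rows = []
        for s in range(10):
            rows.append({"stratum": s, "case": True, "individual": "a", "x": 1.0 + s * 0.01})
            rows.append({"stratum": s, "case": False, "individual": "a", "x": -1.0})
        with pytest.raises(RuntimeError, match="separation"):
            ssf.fit_clogit(ssf.StepSet(pd.DataFrame(rows), ["x"]))

    def test_invariance_to_within_stratum_constant_shift(self):
        ss = tiny_stepset(6, 4, 1, seed=6)
        fit1 = ssf.fit_clogit(ss)
        shifted = ss.data.copy()
        shifted["c0"] = shifted["c0"] + shifted["stratum"] * 7.3
        fit2 = ssf.fit_clogit(ssf.StepSet(shifted, ["c0"]))
        assert fit1.beta[0] == pytest.approx(fit2.beta[0], abs=1e-6)
        assert fit1.log_partial_likelihood == pytest.approx(
            fit2.log_partial_likelihood, abs=1e-6
        )

    def test_multiple_cases_rejected(self):
        ss = tiny_stepset(3, 2, 1)
        bad = ss.data.copy()
        bad.loc[1, "case"] = True
        with pytest.raises(ValueError, match="exactly one case"):
            ssf.fit_clogit(ssf.StepSet(bad, ss.covariate_names))


class TestSsfSurface:
    def make_stack(self):
        g = Grid(4, 4, 1.0)
        return RasterStack(
            {
                "a": Raster(g, np.linspace(0, 1, 16).reshape(4, 4)),
                "b": Raster(g, np.linspace(1, 0, 16).reshape(4, 4)),
            }
        )

    def test_zero_beta_constant(self):
        fit = ssf.FittedSSF(["a", "b"], np.zeros(2), np.ones(2), 0.0, 10)
        surf = ssf.ssf_surface(fit, self.make_stack())
        assert np.allclose(surf.values, 0.5)

    def test_monotone_in_positive_covariate(self):
        fit = ssf.FittedSSF(["a"], np.array([2.0]), np.ones(1), 0.0, 10)
        surf = ssf.ssf_surface(fit, self.make_stack())
        v = surf.values.ravel()
        assert (np.diff(v) >= 0).all()
        assert v.min() == 0.0 and v.max() == 1.0

    def test_probe_dot_product_oracle(self):
        stack = self.make_stack()
        beta = np.array([1.5, -0.7])
        fit = ssf.FittedSSF(["a", "b"], beta, np.ones(2), 0.0, 10)
        surf = ssf.ssf_surface(fit, stack)
        eta = beta[0] * stack["a"].values + beta[1] * stack["b"].values
        s = 1 / (1 + np.exp(-eta))
        expected = (s - s.min()) / (s.max() - s.min())
        assert np.allclose(surf.values, expected)

    def test_missing_layer(self):
        fit = ssf.FittedSSF(["zzz"], np.ones(1), np.ones(1), 0.0, 10)
        with pytest.raises(KeyError):
            ssf.ssf_surface(fit, self.make_stack())


class TestParameterRecovery:
    def test_recovery_and_oracle(self, recovery_fit):
        # reduced scale -> looser tolerance; the acceptance suite runs the
        # full 30x300 design at +-0.15
        fit, beta_true = recovery_fit
        for b, t in zip(fit.beta, beta_true):
            assert abs(b - t) < 0.25

    def test_wald_coverage(self, recovery_fit):
        fit, beta_true = recovery_fit
        lo = fit.beta - 1.96 * fit.se
        hi = fit.beta + 1.96 * fit.se
        assert ((lo <= beta_true) & (beta_true <= hi)).all()


@pytest.fixture(scope="module")
def recovery_fit():
    """Moderate-scale generator-vs-fit round trip (full scale in acceptance)."""
    truth = synth.LandscapeTruth(
        beta_true={"intercept": 0.0, "frac_grass": 1.0, "frac_shrub": -0.5}, master_seed=11
    )
    grid = Grid(120, 120, 100.0)
    pack = synth.make_landscape(truth, grid)
    cov = synth.landscape_covariates(pack, include_terrain=False)
    tracks = synth.simulate_tracks(pack, 12, 200, 4.0, 42, covariates=cov)
    steps = ssf.make_steps(tracks, min_points=100)
    dists = {
        i: ssf.fit_step_distributions(g["length"], g["turn_angle"])
        for i, g in steps.data.groupby("individual")
    }
    aug = ssf.generate_random_steps(steps, dists, grid, k=15, seed=43)
    aug = ssf.attach_covariates(aug, cov, ["frac_grass", "frac_shrub"])
    return ssf.fit_clogit(aug), np.array([1.0, -0.5])
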