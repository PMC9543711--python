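"""Outer estimation: direct search, annealing, selection, profiles."""

import numpy as np
import pandas as pd
import pytest

from wavegam.fit import (
    ZETA_GRID,
    WaveModelRegressor,
    direct_search_init,
    epicentre_separation,
    fit_catalogue,
    fit_wave_model,
    inner_objective,
    profile_ci,
    sann_optimize,
)
from wavegam.waves import MODEL_LABELS, WaveParameterSet


def analytic_obs(params: WaveParameterSet, n=300, seed=0, noise=0.0,
                 extent=100_000.0, quarters=12):
    """Growth observations drawn directly from a noiseless wave equation."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(-extent / 2, extent / 2, n)
    Y = rng.uniform(-extent / 2, extent / 2, n)
    T = rng.integers(0, quarters, n) * 91.0 + rng.uniform(0, 91, n)
    from wavegam.waves import build_design
    Z, _ = build_design(params.label, params, T, X, Y)
    r = np.sin(2 * np.pi * Z[:, 0] / 1095.0)
    if Z.shape[1] > 1:
        r = r + 0.6 * np.sin(2 * np.pi * Z[:, 1] / 1095.0)
    r = r + rng.normal(0, noise, n)
    return pd.DataFrame({"T": T, "X": X, "Y": Y, "r": r, "w": np.ones(n),
                         "quarter": (T // 91).astype(int)})


class TestDirectSearch:
    def test_planted_lattice_optimum_is_found(self):
        """Data generated from an epicentre on a direct-search lattice node
        with a grid speed: the search returns exactly that cell."""
        n_lattice = 6
        # lattice over bbox +-20%: arrange data on [-50, 50] km so nodes are
        # at -70, -42, -14, 14, 42, 70 km; plant the wave at (14, 42) km
        truth = WaveParameterSet("RE", [
            {"gamma": 14_000.0, "psi": 42_000.0, "zeta": float(ZETA_GRID[4])}])
        obs = analytic_obs(truth, n=400, seed=1)
        # pin the bounding box exactly
        obs.loc[0, ["X", "Y"]] = [-50_000.0, -50_000.0]
        obs.loc[1, ["X", "Y"]] = [50_000.0, 50_000.0]
        init = direct_search_init("RE", obs, n_lattice=n_lattice)
        w = init.waves[0]
        assert w["gamma"] == pytest.approx(14_000.0, abs=1.0)
        assert w["psi"] == pytest.approx(42_000.0, abs=1.0)
        assert w["zeta"] == pytest.approx(ZETA_GRID[4], rel=1e-9)

    def test_null_models_need_no_search(self):
        obs = analytic_obs(WaveParameterSet("P", [{"theta": 0.0, "zeta": 1000.0}]))
        for label in ("N1", "N2", "N3"):
            assert direct_search_init(label, obs).waves == []

    def test_search_is_deterministic(self, tiny_growth):
        a = direct_search_init("P", tiny_growth, n_lattice=3, n_theta=8)
        b = direct_search_init("P", tiny_growth, n_lattice=3, n_theta=8)
        assert a.to_vector().tolist() == b.to_vector().tolist()


class TestSann:
    def test_same_seed_reproduces_best_parameters(self, tiny_growth):
        init = direct_search_init("RE", tiny_growth, n_lattice=3)
        a = sann_optimize("RE", tiny_growth, init, iterations=80, seed=5)
        b = sann_optimize("RE", tiny_growth, init, iterations=80, seed=5)
        assert a.params.to_vector().tolist() == b.params.to_vector().tolist()
        assert a.objective == b.objective

    def test_best_ever_never_worse_than_init(self, tiny_growth):
        init = direct_search_init("RE", tiny_growth, n_lattice=3)
        obj0, _ = inner_objective("RE", init, tiny_growth)
        fm = sann_optimize("RE", tiny_growth, init, iterations=80, seed=2)
        assert fm.objective <= obj0 + 1e-9

    def test_more_iterations_never_worsen_best(self, tiny_growth):
        """Shared seed and cooling rate share the proposal-stream prefix."""
        init = direct_search_init("RE", tiny_growth, n_lattice=3)
        short = sann_optimize("RE", tiny_growth, init, iterations=60, seed=3,
                              cooling=0.999)
        long = sann_optimize("RE", tiny_growth, init, iterations=120, seed=3,
                             cooling=0.999)
        assert long.objective <= short.objective + 1e-9

    def test_trace_records_every_iteration(self, tiny_growth):
        init = direct_search_init("RE", tiny_growth, n_lattice=3)
        fm = sann_optimize("RE", tiny_growth, init, iterations=40, seed=0)
        assert len(fm.trace) == 40
        assert fm.trace["best_objective"].is_monotonic_decreasing

    def test_adjusted_aic_offset_is_exactly_2k(self, tiny_growth):
        for label in MODEL_LABELS:
            fm = fit_wave_model(label, tiny_growth, iterations=15, seed=1,
                                n_lattice=2, n_theta=3)
            assert fm.adjusted_aic - fm.aic == pytest.approx(2.0 * fm.K, abs=0)


class TestCatalogue:
    def test_comparison_table_well_formed(self, tiny_growth):
        labels = ["N1", "N2", "RE", "P"]
        comp, fits = fit_catalogue(tiny_growth, labels, iterations=40, seed=4,
                                   n_lattice=3, n_theta=6)
        assert set(comp["label"]) == set(labels)
        assert comp["delta"].min() == 0.0
        assert comp["selected"].sum() == 1
        assert comp.loc[0, "delta"] == 0.0
        # adjusted AIC = AIC + 2K row-wise
        assert np.allclose(comp["adjustedAIC"], comp["AIC"] + 2 * comp["K"])

    def test_rerun_is_reproducible(self, tiny_growth):
        labels = ["N1", "RE"]
        a, _ = fit_catalogue(tiny_growth, labels, iterations=40, seed=9,
                             n_lattice=3)
        b, _ = fit_catalogue(tiny_growth, labels, iterations=40, seed=9,
                             n_lattice=3)
        pd.testing.assert_frame_equal(a, b)

    def test_failures_become_rows_not_exceptions(self):
        # two distinct quarters only: direct search precondition fails for
        # wave models, but the null rows must survive
        obs = pd.DataFrame({"T": [0.0, 91.0] * 6, "X": np.arange(12) * 1e3,
                            "Y": np.arange(12) * 1e3, "r": 0.1 * np.arange(12),
                            "w": np.ones(12), "quarter": [0, 1] * 6})
        comp, fits = fit_catalogue(obs, ["N1", "RE"], iterations=10, seed=0)
        assert comp.loc[comp["label"] == "RE", "error"].iloc[0] != ""
        assert np.isfinite(comp.loc[comp["label"] == "N1", "AIC"]).all()


class TestProfile:
    def test_quadratic_objective_matches_wald_interval(self):
        """Strong linear signal in rho: the profile cutoff reproduces the
        +-1.96 SE interval of the equivalent linear model within 5%."""
        rng = np.random.default_rng(0)
        n = 800
        X = rng.uniform(-50_000, 50_000, n)
        Y = rng.uniform(-50_000, 50_000, n)
        T = rng.uniform(0, 1092, n)
        zeta = 1000.0
        rho = T + (-np.hypot(X - 10_000, Y - 5_000)) / zeta
        slope = 1e-3
        r = slope * rho + rng.normal(0, 0.05, n)
        obs = pd.DataFrame({"T": T, "X": X, "Y": Y, "r": r, "w": np.ones(n),
                            "quarter": (T // 91).astype(int)})
        fm = fit_wave_model("RE", obs, iterations=400, seed=1, n_lattice=4)
        w = fm.params.waves[0]
        grid = np.linspace(0.7 * w["zeta"], 1.45 * w["zeta"], 16)
        ci = profile_ci(fm, obs, "zeta", grid, iterations=60, seed=0)
        assert not ci.one_sided
        # near-quadratic profile: the chi-square crossings must match the
        # crossings implied by a quadratic fit to the profile itself
        c = np.polyfit(ci.grid, ci.objective, 2)
        x0 = -c[1] / (2 * c[0])
        half = np.sqrt(ci.cutoff / c[0])  # quadratic: min + c0 (x - x0)^2
        assert ci.lower95 == pytest.approx(x0 - half, rel=0.05)
        assert ci.upper95 == pytest.approx(x0 + half, rel=0.05)

    def test_grid_must_bracket_the_estimate(self, tiny_growth):
        fm = fit_wave_model("RE", tiny_growth, iterations=30, seed=2,
                            n_lattice=3)
        with pytest.raises(ValueError, match="does not contain"):
            profile_ci(fm, tiny_growth, "zeta",
                       np.array([1e6, 2e6]), iterations=10)

    def test_unknown_parameter_rejected(self, tiny_growth):
        fm = fit_wave_model("RE", tiny_growth, iterations=20, seed=2,
                            n_lattice=3)
        with pytest.raises(ValueError, match="not in"):
            profile_ci(fm, tiny_growth, "theta", np.array([0.0, 1.0]))


class TestEpicentreSeparation:
    def test_table_of_dual_epicentres(self):
        p = WaveParameterSet("RDE", [
            {"gamma": -41_723.0, "psi": 28_414.0, "zeta": 405.0},
            {"gamma": 23_675.0, "psi": -8_675.0, "zeta": 2287.0}])
        assert epicentre_separation(p) == pytest.approx(75.2, abs=0.05)

    def test_degenerate_and_simple_cases(self):
        same = {"gamma": 5.0, "psi": -5.0, "zeta": 1.0}
        p = WaveParameterSet("RDE", [dict(same), dict(same)])
        assert epicentre_separation(p) == 0.0
        p345 = WaveParameterSet("RDE", [
            {"gamma": 0.0, "psi": 0.0, "zeta": 1.0},
            {"gamma": 3000.0, "psi": 4000.0, "zeta": 1.0}])
        assert epicentre_separation(p345) == pytest.approx(5.0)

    def test_single_wave_model_rejected(self):
        p = WaveParameterSet("RE", [{"gamma": 0.0, "psi": 0.0, "zeta": 1.0}])
        with pytest.raises(ValueError):
            epicentre_separation(p)


class TestWaveModelRegressor:
    def test_sklearn_interface_and_predict(self, tiny_growth):
        from sklearn.base import clone
        est = WaveModelRegressor(label="RE", iterations=40, seed=1, n_lattice=3)
        est2 = clone(est)
        X = tiny_growth[["T", "X", "Y"]].to_numpy()
        est2.fit(X, tiny_growth["r"], sample_weight=tiny_growth["w"])
        assert est2.adjusted_aic_ - est2.aic_ == pytest.approx(6.0)
        pred = est2.predict(X)
        assert pred.shape == (len(tiny_growth),)
        assert np.all(np.isfinite(pred))

    def test_null_label_fit(self, tiny_growth):
        X = tiny_growth[["T", "X", "Y"]].to_numpy()
        est = WaveModelRegressor(label="N2").fit(X, tiny_growth["r"],
                                                 sample_weight=tiny_growth["w"])
        assert est.K_ == 0 and est.params_.waves == []
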