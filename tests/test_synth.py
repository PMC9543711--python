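"""Synthetic growth fields and survey generation."""

import warnings

import numpy as np
import pytest

from wavegam.synth import (
    INDEX_OFFSET,
    SamplingDesign,
    Wave,
    WaveFieldSpec,
    evaluate_growth_field,
    generate_surveys,
    integrated_growth,
    noise_free_index,
    read_surveys,
    simulate_index_series,
    write_surveys,
)


def radial_wave(zeta=500.0, gamma=50_000.0, psi=40_000.0, **kw):
    return Wave("radial-expanding", zeta=zeta, gamma=gamma, psi=psi, **kw)


class TestGrowthField:
    def test_interceptonly_field_is_constant(self):
        spec = WaveFieldSpec(waves=[], alpha1=0.2)
        assert evaluate_growth_field(spec, 1e5, -3e4, 77.0) == pytest.approx(0.2)

    def test_epicentre_sees_the_undelayed_cycle(self):
        spec = WaveFieldSpec(waves=[radial_wave()], alpha1=0.1)
        day = 300.0
        expected = 0.1 + 1.5 * np.sin(2 * np.pi * day / spec.period)
        got = evaluate_growth_field(spec, 50_000.0, 40_000.0, day)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_field_translates_along_the_wave(self):
        """Value at distance d equals the epicentre's value at day - d/zeta."""
        spec = WaveFieldSpec(waves=[radial_wave()])
        w = spec.waves[0]
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.uniform(0, 2e5), rng.uniform(0, 1.5e5)
            t = rng.uniform(0, spec.duration)
            d = np.hypot(x - w.gamma, y - w.psi)
            at_point = evaluate_growth_field(spec, x, y, t)
            at_epi_shifted = evaluate_growth_field(spec, w.gamma, w.psi, t - d / w.zeta)
            assert at_point == pytest.approx(at_epi_shifted, abs=1e-9)

    def test_huge_speed_gives_spatial_synchrony(self):
        spec = WaveFieldSpec(waves=[radial_wave(zeta=1e12)])
        vals = evaluate_growth_field(
            spec, np.array([0.0, 1e5, 2e5]), np.array([0.0, 1.5e5, 5e4]), 500.0)
        assert np.ptp(vals) < 1e-6

    def test_dual_field_is_additive(self):
        w1 = radial_wave()
        w2 = Wave("radial-contracting", zeta=2000.0, gamma=150_000.0,
                  psi=100_000.0, amplitude=0.8)
        dual = WaveFieldSpec(waves=[w1, w2], alpha1=0.3)
        f1 = WaveFieldSpec(waves=[w1], alpha1=0.0)
        f2 = WaveFieldSpec(waves=[w2], alpha1=0.0)
        x, y, t = 20_000.0, 90_000.0, 444.0
        assert evaluate_growth_field(dual, x, y, t) == pytest.approx(
            0.3 + evaluate_growth_field(f1, x, y, t)
            + evaluate_growth_field(f2, x, y, t), abs=1e-12)

    def test_unknown_wave_form_rejected(self):
        with pytest.raises(ValueError):
            Wave("spiral", zeta=1.0)


class TestIndexSeries:
    def test_zero_field_keeps_index_constant(self):
        spec = WaveFieldSpec(waves=[], alpha1=0.0)
        out = simulate_index_series(spec, 0.0, 0.0, [0.0, 91.0, 182.0],
                                    baseline=12.0)
        assert np.allclose(out, 12.0)

    def test_one_quarter_of_ln10_growth_from_zero(self):
        """Inverting r = ln(N'+c) - ln(N+c): 0 -> 10*(0+3.03) - 3.03."""
        spec = WaveFieldSpec(waves=[], alpha1=np.log(10.0))
        out = simulate_index_series(spec, 0.0, 0.0, [0.0, 91.0], baseline=0.0)
        assert out[1] == pytest.approx(27.27, abs=1e-10)

    def test_overflow_clips_to_100_with_warning(self):
        spec = WaveFieldSpec(waves=[], alpha1=np.log(10.0))
        with pytest.warns(UserWarning, match="clipped"):
            out = simulate_index_series(spec, 0.0, 0.0, [0.0, 91.0],
                                        baseline=50.0)
        assert out[1] == 100.0

    def test_days_must_increase(self):
        spec = WaveFieldSpec()
        with pytest.raises(ValueError):
            simulate_index_series(spec, 0.0, 0.0, [10.0, 10.0])

    def test_noise_free_index_logdiff_recovers_integrated_growth(self):
        """With no clipping, quarterly log-differences equal the field's
        integrated growth to machine precision."""
        spec = WaveFieldSpec(waves=[radial_wave(amplitude=0.15)])
        x, y = 30_000.0, 40_000.0
        i1 = noise_free_index(spec, x, y, 100.0)
        i2 = noise_free_index(spec, x, y, 191.0)
        r_obs = np.log(i2 + INDEX_OFFSET) - np.log(i1 + INDEX_OFFSET)
        r_true = integrated_growth(spec, x, y, 100.0, 191.0)
        assert r_obs == pytest.approx(r_true, abs=1e-12)


class TestGenerateSurveys:
    def test_same_seed_reproduces_identical_tables(self):
        spec = WaveFieldSpec(waves=[radial_wave()])
        design = SamplingDesign(n_surveys_per_quarter=50, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = generate_surveys(spec, design)
            b = generate_surveys(spec, design)
        assert a.equals(b)

    def test_survey_count_and_day_bounds(self):
        spec = WaveFieldSpec(waves=[radial_wave()], duration=8 * 91.0)
        design = SamplingDesign(n_surveys_per_quarter=400, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = generate_surveys(spec, design)
        assert len(df) == 3200
        q = (df["day"] // 91).astype(int)
        assert q.value_counts().eq(400).all()
        # jittered inside quarters, never on a boundary
        assert (df["day"] % 91.0 > 0).all() and (df["day"] % 91.0 < 91).all()
        assert df["index"].between(0, 100).all()

    def test_adaptive_design_concentrates_effort_in_core(self):
        """Mean surveys per unit area strictly higher inside the core,
        across 20 independent seeds."""
        spec = WaveFieldSpec(waves=[radial_wave()], duration=8 * 91.0)
        core = (80_000.0, 120_000.0, 60_000.0, 90_000.0)
        core_area = (120_000 - 80_000) * (90_000 - 60_000)
        total_area = 200_000 * 150_000
        wins = 0
        for seed in range(20):
            design = SamplingDesign(mode="adaptive", n_surveys_per_quarter=60,
                                    core_region=core, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                df = generate_surveys(spec, design)
            in_core = (df["x"].between(core[0], core[1])
                       & df["y"].between(core[2], core[3]))
            dens_in = in_core.sum() / core_area
            dens_out = (~in_core).sum() / (total_area - core_area)
            wins += dens_in > dens_out
        assert wins == 20

    def test_too_short_duration_is_rejected(self):
        spec = WaveFieldSpec(waves=[radial_wave()], duration=100.0)
        with pytest.raises(ValueError, match="two quarters"):
            generate_surveys(spec, SamplingDesign(n_surveys_per_quarter=5))

    def test_design_validation(self):
        with pytest.raises(ValueError):
            SamplingDesign(n_surveys_per_quarter=0)
        with pytest.raises(ValueError):
            SamplingDesign(mode="adaptive", core_region=None)
        with pytest.raises(ValueError):
            SamplingDesign(core_fraction=1.5, mode="uniform")


def test_survey_roundtrip_with_metadata(tmp_path):
    spec = WaveFieldSpec(waves=[radial_wave()], duration=4 * 91.0)
    design = SamplingDesign(n_surveys_per_quarter=20, seed=9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df = generate_surveys(spec, design)
    path = tmp_path / "surveys.csv"
    write_surveys(df, path, spec, design)
    back = read_surveys(path)
    assert np.allclose(back["index"], df["index"])
    assert (path.parent / "surveys.meta.yaml").exists()
    import yaml
    meta = yaml.safe_load((path.parent / "surveys.meta.yaml").read_text())
    assert meta["seed"] == 9 and meta["waves"][0]["zeta"] == 500.0


def test_field_spec_validation():
    with pytest.raises(ValueError):
        WaveFieldSpec(period=-1.0)
    with pytest.raises(ValueError):
        WaveFieldSpec(sigma=-0.1)
    with pytest.raises(ValueError):
        WaveFieldSpec(extent=(0.0, 0.0, 0.0, 1.0))
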