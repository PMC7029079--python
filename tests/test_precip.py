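import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasticlim.errors import DomainError, InsufficientDataError
from plasticlim.precip import (
    FitnessLandscape,
    ModelConfig,
    PrecipStrategy,
    bimodality_condition,
    evaluate_precip_landscape,
    fitness_year,
    geometric_mean_fitness,
    predict_precip_phenotype,
)
from plasticlim.synthetic import AnnualSimSpec, simulate_annual_series
from plasticlim.tstats import SiteClimateSummary, site_summary

from conftest import make_annual
from oracles import precip_gm_direct


class TestPrecipStrategy:
    def test_zero_m_canonicalizes_g(self):
        assert PrecipStrategy(0.0, 0.7).g == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            PrecipStrategy(1.5, 0.0)
        with pytest.raises(DomainError):
            PrecipStrategy(0.5, -0.1)

    def test_lag_weights_normalized(self):
        w = PrecipStrategy(0.5, 0.5).lag_weights
        assert w.sum() == pytest.approx(1.0)
        assert np.allclose(w, np.array([1.0, 0.5, 0.25]) / 1.75)


class TestPredictPrecipPhenotype:
    # mean exactly 100; year index 7 sees prior deviations (+20, -20, 0)
    series = make_annual([100, 100, 100, 100, 100, 80, 120, 100])

    def test_m_zero_gives_baseline(self):
        for t in range(3, 8):
            assert predict_precip_phenotype(self.series, PrecipStrategy(0.0), t) == 100.0

    def test_m_one_g_zero_gives_previous_year(self):
        s = PrecipStrategy(1.0, 0.0)
        for t in range(3, 8):
            assert predict_precip_phenotype(self.series, s, t) == pytest.approx(
                self.series.values[t - 1]
            )

    def test_symmetric_deviations_cancel_at_g_one(self):
        assert predict_precip_phenotype(
            self.series, PrecipStrategy(0.5, 1.0), 7
        ) == pytest.approx(100.0)

    def test_hand_computed_weighted_case(self):
        # 100 + 0.4*(20 - 0.5*20 + 0)/(1 + 0.5 + 0.25) = 102.2857...
        got = predict_precip_phenotype(self.series, PrecipStrategy(0.4, 0.5), 7)
        assert got == pytest.approx(100 + 0.4 * 10 / 1.75, abs=1e-12)

    def test_early_index_rejected(self):
        with pytest.raises(IndexError):
            predict_precip_phenotype(self.series, PrecipStrategy(0.1), 2)

    def test_gap_in_history_rejected(self):
        gappy = make_annual([100, 90, 110, 100, 100, 100],
                            years=[2000, 2001, 2003, 2004, 2005, 2006])
        with pytest.raises(IndexError):
            predict_precip_phenotype(gappy, PrecipStrategy(0.1), 3)
        assert predict_precip_phenotype(gappy, PrecipStrategy(0.0), 5) == pytest.approx(
            gappy.baseline
        )


class TestFitnessYear:
    def test_perfect_match(self):
        assert fitness_year(100.0, 100.0, 100.0) == 1.0

    def test_linear_cost(self):
        assert fitness_year(80.0, 100.0, 100.0) == pytest.approx(0.8)

    def test_floor_applies(self):
        assert fitness_year(300.0, 100.0, 100.0, eps=1e-6) == 1e-6

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DomainError):
            fitness_year(1.0, 1.0, 0.0)


class TestGeometricMeanFitness:
    def test_constant_series_every_strategy_wins(self):
        series = make_annual(np.full(12, 250.0))
        for m, g in [(0.0, 0.0), (1.0, 0.0), (-0.5, 0.5), (0.3, 1.0)]:
            sf = geometric_mean_fitness(series, PrecipStrategy(m, g))
            assert sf.gm_fitness == pytest.approx(1.0)
            assert sf.n_years_used == 9

    def test_toy_hand_computed_product(self):
        # m=0: usable years have w = 0.8 and 0.2, so W = sqrt(0.16) = 0.4
        series = make_annual([50.0, 50.0, 100.0, 120.0, 180.0])
        with pytest.raises(InsufficientDataError):
            geometric_mean_fitness(series, PrecipStrategy(0.0))
        padded = make_annual([100.0, 100.0, 100.0, 50.0, 50.0, 100.0, 120.0, 180.0])
        assert padded.baseline == pytest.approx(100.0)
        sf = geometric_mean_fitness(padded, PrecipStrategy(0.0))
        # usable years: indices 3..7 with w = 0.5, 0.5, 1.0, 0.8, 0.2
        expected = (0.5 * 0.5 * 1.0 * 0.8 * 0.2) ** (1 / 5)
        assert sf.gm_fitness == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 80))
            series = make_annual(500.0 + 60.0 * rng.standard_normal(n))
            for _ in range(10):
                m = float(rng.uniform(-1, 1))
                g = float(rng.uniform(0, 1))
                got = geometric_mean_fitness(series, PrecipStrategy(m, g)).gm_fitness
                want = precip_gm_direct(series, m, g if m != 0 else 0.0)
                assert got == pytest.approx(want, abs=1e-12)

    @given(seed=st.integers(min_value=0, max_value=2**31), m=st.floats(-1, 1),
           g=st.floats(0, 1))
    @settings(max_examples=30, deadline=None)
    def test_fitness_bounded(self, seed, m, g):
        rng = np.random.default_rng(seed)
        series = make_annual(200.0 + 150.0 * rng.standard_normal(20))
        if series.values.mean() <= 0:
            return
        sf = geometric_mean_fitness(series, PrecipStrategy(m, g))
        assert 1e-6 <= sf.gm_fitness <= 1.0


class TestEvaluatePrecipLandscape:
    def test_grid_covers_canonical_lattice_once(self, rng):
        series = make_annual(400 + 40 * rng.standard_normal(40))
        land = evaluate_precip_landscape(series)
        assert isinstance(land, FitnessLandscape)
        # 20 nonzero m values x 11 g values + one canonical m=0 point
        assert len(land.grid) == 221
        keys = {(sf.strategy.m, sf.strategy.g) for sf in land.grid}
        assert len(keys) == 221
        assert (0.0, 0.0) in keys

    def test_optimum_is_a_local_maximum(self, rng):
        for seed in range(5):
            series = simulate_annual_series(
                AnnualSimSpec(n_years=120, mean=700, sd=100,
                              pacf_targets=(0.3,), seed=seed)
            )
            land = evaluate_precip_landscape(series)
            assert any(sf.strategy == land.optimum.strategy for sf in land.local_maxima)
            assert land.optimum.gm_fitness == max(sf.gm_fitness for sf in land.grid)

    def test_white_noise_prefers_no_plasticity(self):
        hits = 0
        for seed in range(25):
            series = simulate_annual_series(
                AnnualSimSpec(n_years=1000, mean=800, sd=80, seed=seed)
            )
            if evaluate_precip_landscape(series).optimum.strategy.m == 0.0:
                hits += 1
        assert hits > 12

    def test_positive_coupling_recovered(self):
        hits = 0
        for seed in range(10):
            series = simulate_annual_series(
                AnnualSimSpec(n_years=2000, mean=1000, sd=50,
                              pacf_targets=(0.6,), seed=seed)
            )
            m_opt = evaluate_precip_landscape(series).optimum.strategy.m
            if abs(m_opt - 0.6) < 0.15:
                hits += 1
        assert hits > 5

    def test_negative_coupling_gives_negative_m(self):
        hits = 0
        for seed in range(10):
            series = simulate_annual_series(
                AnnualSimSpec(n_years=2000, mean=1000, sd=50,
                              pacf_targets=(-0.3,), seed=seed)
            )
            if evaluate_precip_landscape(series).optimum.strategy.m < 0:
                hits += 1
        assert hits > 5

    def test_residual_variant_removes_trend_benefit(self):
        raw_ms, res_ms = [], []
        for seed in range(20):
            series = simulate_annual_series(
                AnnualSimSpec(n_years=119, mean=800, sd=50, trend=1.5, seed=seed)
            )
            raw_ms.append(
                evaluate_precip_landscape(series, ModelConfig(variant="raw"))
                .optimum.strategy.m
            )
            res_ms.append(
                evaluate_precip_landscape(series, ModelConfig(variant="residual"))
                .optimum.strategy.m
            )
        assert np.mean(raw_ms) >= np.mean(res_ms)

    def test_m_zero_column_is_flat(self, rng):
        series = make_annual(600 + 90 * rng.standard_normal(50))
        land = evaluate_precip_landscape(series)
        i0 = land.m_grid.index(0.0)
        assert len(set(land.fitness[i0, :])) == 1


def summary_stub(acf1, pacf2, pacf3):
    acf_vals = np.full(12, np.nan)
    pacf_vals = np.full(12, np.nan)
    acf_vals[0] = acf1
    pacf_vals[0] = acf1
    pacf_vals[1] = pacf2
    pacf_vals[2] = pacf3
    return SiteClimateSummary(
        site_id="s", variable="precip", mean=1.0, iasd=1.0, trend_slope=0.0,
        acf=acf_vals, pacf=pacf_vals, res_acf1=np.nan, n_years=120,
    )


class TestBimodalityCondition:
    def test_opposing_small_acf1_true(self):
        assert bimodality_condition(summary_stub(-0.05, 0.2, 0.2)) is True

    def test_same_sign_false(self):
        assert bimodality_condition(summary_stub(0.3, 0.1, 0.1)) is False

    def test_larger_magnitude_acf1_false(self):
        assert bimodality_condition(summary_stub(-0.3, 0.1, 0.1)) is False

    def test_missing_inputs_raise(self):
        with pytest.raises(DomainError):
            bimodality_condition(summary_stub(np.nan, 0.1, 0.1))

    def test_condition_sites_often_bimodal(self):
        bimodal = 0
        for seed in range(15):
            series = simulate_annual_series(
                AnnualSimSpec(n_years=500, mean=1000, sd=100,
                              pacf_targets=(-0.15, 0.25, 0.25), seed=seed)
            )
            land = evaluate_precip_landscape(series)
            if land.n_local_maxima >= 2:
                bimodal += 1
        assert bimodal > 7
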