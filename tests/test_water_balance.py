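import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drylandsim.synthetic_data import (WeatherGenParams, apply_monthly_normals,
                                       gen_daily_weather, gen_soil_profile)
from drylandsim.vegetation import build_vegetation
from drylandsim.water_balance import (SoilLayer, WaterBalanceParams,
                                      bare_soil_evap, day_length_hours,
                                      hydraulic_redistribute,
                                      infiltrate_and_percolate, intercept,
                                      melt_snow, partition_precip_snow,
                                      pet_daily, simulate, swp_from_theta,
                                      theta_from_swp, transpire)


@pytest.fixture
def layer():
    return SoilLayer.from_texture(0, 20, sand=0.4, clay=0.2)


class TestSoilLayer:
    @pytest.mark.parametrize("sand,clay", [(0.1, 0.1), (0.4, 0.2), (0.8, 0.1),
                                           (0.2, 0.5), (0.95, 0.03)])
    def test_texture_regression_orders_parameters(self, sand, clay):
        l = SoilLayer.from_texture(0, 20, sand, clay)
        assert 0 < l.wilting_point < l.field_capacity < l.theta_sat
        assert l.psi_sat < 0 and l.b > 0

    def test_texture_contrast(self):
        sandy = SoilLayer.from_texture(0, 20, 0.8, 0.05)
        clayey = SoilLayer.from_texture(0, 20, 0.2, 0.45)
        # equal relative content: psi/psi_sat follows the closed form
        rel = 0.6
        assert swp_from_theta(rel * sandy.theta_sat, sandy) / sandy.psi_sat \
            == pytest.approx(rel ** -sandy.b)
        # at equal absolute theta the clay layer is drier (more negative)
        theta = 0.25
        assert swp_from_theta(theta, clayey) < swp_from_theta(theta, sandy)

    def test_invalid_geometry_raises(self):
        with pytest.raises(ValueError):
            SoilLayer.from_texture(20, 10, 0.4, 0.2)


class TestRetentionCurve:
    def test_saturation_returns_air_entry(self, layer):
        assert swp_from_theta(layer.theta_sat, layer) == \
            pytest.approx(layer.psi_sat)

    def test_halving_theta_scales_by_2_to_b(self, layer):
        theta = 0.8 * layer.theta_sat
        ratio = swp_from_theta(theta / 2, layer) / swp_from_theta(theta, layer)
        assert ratio == pytest.approx(2 ** layer.b)

    def test_strictly_increasing_in_theta(self, layer):
        thetas = np.linspace(0.05, layer.theta_sat, 50)
        psi = swp_from_theta(thetas, layer)
        assert np.all(np.diff(psi) > 0)

    def test_nonpositive_theta_raises(self, layer):
        with pytest.raises(ValueError):
            swp_from_theta(0.0, layer)

    @given(rel=st.floats(0.05, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_roundtrip_with_inverse(self, rel):
        layer = SoilLayer.from_texture(0, 20, sand=0.4, clay=0.2)
        theta = rel * layer.theta_sat
        assert theta_from_swp(swp_from_theta(theta, layer), layer) == \
            pytest.approx(theta, rel=1e-9)


class TestPet:
    ARGS = dict(rh_pct=50.0, wind_ms=2.0, cloud_frac=0.3)

    def test_correction_factor_scales_output(self):
        raw = pet_daily(180, 40, 25, 10, correction=1.0, **self.ARGS)
        corrected = pet_daily(180, 40, 25, 10, correction=1.2, **self.ARGS)
        assert corrected == pytest.approx(1.2 * raw)

    def test_longer_day_means_more_pet(self):
        # same temperatures at summer vs winter solstice, lat 45 N
        long_day = pet_daily(172, 45, 20, 8, **self.ARGS)
        short_day = pet_daily(355, 45, 20, 8, **self.ARGS)
        assert day_length_hours(172, 45) > 14 > 10 > day_length_hours(355, 45)
        assert long_day > short_day

    def test_polar_night_near_zero(self):
        pet = pet_daily(355, 80, -15, -25, **self.ARGS)
        assert 0 <= pet < 0.05

    def test_increasing_in_temperature(self):
        for doy, lat in [(172, 45), (100, 0), (30, -30)]:
            pets = [pet_daily(doy, lat, t + 5, t - 5, **self.ARGS)
                    for t in np.arange(-5, 40, 2.5)]
            assert np.all(np.diff(pets) > 0)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pet = pet_daily(int(rng.integers(1, 366)), rng.uniform(-90, 90),
                            rng.uniform(-30, 45), rng.uniform(-40, 35),
                            rng.uniform(10, 100), rng.uniform(0, 10),
                            rng.uniform(0, 1))
            assert pet >= 0

    def test_invalid_latitude_raises(self):
        with pytest.raises(ValueError):
            pet_daily(100, 95, 20, 10, **self.ARGS)


class TestSnow:
    def test_cold_day_all_snow(self):
        assert partition_precip_snow(10, -5) == (0.0, 10.0)

    def test_warm_day_all_rain(self):
        assert partition_precip_snow(10, 5) == (10.0, 0.0)

    def test_rain_plus_snow_equals_precip(self):
        for t in (-10, -0.1, 0, 3):
            rain, snow = partition_precip_snow(7.5, t)
            assert rain + snow == 7.5 and min(rain, snow) == 0.0

    def test_melt_capped_by_pack(self):
        assert melt_snow(3.0, 20.0, melt_coeff=2.0) == 3.0

    def test_degree_day_arithmetic(self):
        assert melt_snow(100.0, 2.0, melt_coeff=2.0) == pytest.approx(4.0)

    def test_no_melt_below_threshold(self):
        assert melt_snow(100.0, -2.0) == 0.0


class TestInterception:
    def test_no_vegetation_no_interception(self):
        assert intercept(10.0, 0.0, 0.0) == (0.0, 10.0)

    def test_supply_cap(self):
        # capacity 2 mm (800 g/m2 * 0.0025), only 1 mm falls
        loss, through = intercept(1.0, 700.0, 100.0)
        assert loss == 1.0 and through == 0.0

    def test_capacity_rule(self):
        loss, through = intercept(10.0, 700.0, 100.0)
        assert loss == pytest.approx(2.0) and through == pytest.approx(8.0)


class TestInfiltration:
    def test_zero_input_noop(self, profile):
        theta0 = profile.array("wilting_point")
        theta, perc, drain = infiltrate_and_percolate(0.0, theta0, profile)
        assert np.array_equal(theta, theta0) and drain == 0.0
        assert np.all(perc == 0)

    def test_small_input_stays_in_top_layer(self, profile):
        theta0 = profile.array("wilting_point")
        l0 = profile.layers[0]
        deficit0 = (l0.field_capacity - l0.wilting_point) * l0.thickness_mm
        theta, perc, drain = infiltrate_and_percolate(0.5 * deficit0, theta0,
                                                      profile)
        assert theta[0] > theta0[0]
        assert np.array_equal(theta[1:], theta0[1:])
        assert drain == 0.0

    def test_overflow_becomes_deep_drainage(self, profile):
        theta0 = profile.array("wilting_point")
        deficit = float(np.sum((profile.array("field_capacity") - theta0)
                               * profile.thickness_mm))
        theta, _, drain = infiltrate_and_percolate(deficit + 25.0, theta0,
                                                   profile)
        assert drain == pytest.approx(25.0)
        assert theta == pytest.approx(profile.array("field_capacity"))

    @given(water=st.floats(0, 500), fill=st.floats(0, 1))
    @settings(max_examples=40, deadline=None)
    def test_mass_conservation(self, profile, water, fill):
        wp, fc = profile.array("wilting_point"), profile.array("field_capacity")
        theta0 = wp + fill * (fc - wp)
        theta, _, drain = infiltrate_and_percolate(water, theta0, profile)
        stored = float(np.sum((theta - theta0) * profile.thickness_mm))
        assert stored + drain == pytest.approx(water, abs=1e-9)


class TestBareSoilEvap:
    def test_saturated_surface_unstressed(self, profile):
        theta = profile.array("field_capacity")
        evap, _ = bare_soil_evap(theta, 4.0, profile)
        assert evap == pytest.approx(4.0)

    def test_dry_limit_shuts_down(self, profile):
        theta = np.array([theta_from_swp(-15.0, l) for l in profile.layers])
        evap, _ = bare_soil_evap(theta, 4.0, profile)
        assert evap == pytest.approx(0.0, abs=1e-9)

    def test_intermediate_stress_factor(self, profile):
        from drylandsim.water_balance import _group_mean_swp, _swp_stress
        wp, fc = profile.array("wilting_point"), profile.array("field_capacity")
        theta = wp + 0.5 * (fc - wp)
        idx = np.where(profile.array("depth_top") < 15.0)[0]
        psi = _group_mean_swp(theta, profile, idx)
        expected = float(_swp_stress(psi, -0.033, -15.0)) * 4.0
        evap, _ = bare_soil_evap(theta, 4.0, profile)
        assert evap == pytest.approx(expected)

    def test_only_surface_layers_touched(self, profile):
        theta0 = profile.array("field_capacity")
        _, theta = bare_soil_evap(theta0, 4.0, profile, evap_depth_cm=15.0)
        deep = profile.array("depth_top") >= 15.0
        assert np.array_equal(theta[deep], theta0[deep])


class TestTranspire:
    def _setup(self, profile):
        comp = {"shrub": 0.5, "c3": 0.5, "c4": 0.0}
        live = {"shrub": 1.0, "c3": 1.0, "c4": 1.0}
        n = len(profile)
        roots = {g: np.full(n, 1.0 / n) for g in comp}
        crit = {"shrub": -3.9, "c3": -3.5, "c4": -3.5}
        return comp, live, roots, crit

    def test_zero_root_layer_gets_zero_uptake(self, profile):
        comp, live, roots, crit = self._setup(profile)
        for g in roots:
            roots[g] = np.zeros(len(profile))
            roots[g][0] = 1.0
        theta = profile.array("field_capacity")
        uptake, _ = transpire(theta, 5.0, comp, live, roots, crit, profile)
        assert np.all(uptake[:, 1:] == 0)

    def test_full_stress_stops_transpiration(self, profile):
        comp, live, roots, crit = self._setup(profile)
        theta = np.array([theta_from_swp(-4.0, l) for l in profile.layers])
        uptake, _ = transpire(theta, 5.0, comp, live, roots, crit, profile)
        assert np.all(uptake == 0)

    def test_uptake_concentrates_in_wet_layer(self, profile):
        comp, live, roots, crit = self._setup(profile)
        theta = profile.array("field_capacity").copy()
        theta[0] = theta_from_swp(-3.2, profile.layers[0])  # dry surface
        uptake, _ = transpire(theta, 5.0, comp, live, roots, crit, profile)
        per_layer = uptake.sum(axis=0)
        assert per_layer[1] > per_layer[0]

    def test_total_bounded_by_potential(self, profile):
        comp, live, roots, crit = self._setup(profile)
        theta = profile.array("field_capacity")
        uptake, _ = transpire(theta, 5.0, comp, live, roots, crit, profile)
        assert uptake.sum() <= 5.0 + 1e-12


class TestHydraulicRedistribution:
    def test_uniform_potential_no_flux(self, profile):
        theta = 0.7 * profile.array("theta_sat")
        rel = theta / profile.array("theta_sat")
        # uniform texture: equal relative content = equal psi
        assert np.ptp(rel) == 0
        flux, _ = hydraulic_redistribute(theta, profile,
                                         np.full(len(profile), 0.2))
        assert np.all(flux == 0)

    def test_wet_deep_dry_surface_moves_up(self, profile):
        theta = profile.array("field_capacity").copy()
        theta[0] = theta_from_swp(-3.0, profile.layers[0])
        theta[1] = theta_from_swp(-3.0, profile.layers[1])
        flux, _ = hydraulic_redistribute(theta, profile,
                                         np.full(len(profile), 0.2))
        assert flux[0] > 0  # surface receives water

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_fluxes_sum_to_zero(self, profile, seed):
        rng = np.random.default_rng(seed)
        wp, fc = profile.array("wilting_point"), profile.array("field_capacity")
        theta = wp + rng.random(len(profile)) * (fc - wp)
        flux, theta_new = hydraulic_redistribute(theta, profile,
                                                 rng.random(len(profile)))
        assert abs(flux.sum()) < 1e-9
        assert np.all(theta_new <= fc + 1e-12)
        assert np.all(theta_new >= wp - 1e-12)


class TestSimulate:
    def _atmos(self):
        return np.full(12, 55.0), np.full(12, 2.5), np.full(12, 0.4)

    def test_determinism(self, dryland_weather, profile, vegetation):
        rh, wind, cloud = self._atmos()
        a = simulate(dryland_weather, profile, vegetation, 40.0, rh, wind, cloud)
        b = simulate(dryland_weather, profile, vegetation, 40.0, rh, wind, cloud)
        pd.testing.assert_frame_equal(a.daily, b.daily)
        assert np.array_equal(a.theta, b.theta)

    def test_daily_closure(self, sim_result):
        assert np.abs(sim_result.daily["residual"]).max() < 1e-6

    def test_theta_stays_in_bounds(self, sim_result, profile):
        theta_sat = profile.array("theta_sat")
        assert np.all(sim_result.theta <= theta_sat + 1e-12)
        assert np.all(sim_result.theta > 0)

    def test_zero_precip_monotone_drying(self, dryland_weather, profile,
                                         vegetation):
        w = dryland_weather.copy()
        w["precip"] = 0.0
        rh, wind, cloud = self._atmos()
        res = simulate(w, profile, vegetation, 40.0, rh, wind, cloud)
        storage = res.daily["storage"].to_numpy()
        assert np.all(np.diff(storage) <= 1e-9)
        assert res.daily["drainage"].sum() == 0.0

    def test_aet_bounded_by_pet_and_supply(self, sim_result):
        daily = sim_result.daily
        years = daily["date"].dt.year
        annual = daily.groupby(years)[["pet", "precip", "evap", "transp",
                                       "interception"]].sum()
        aet = annual["evap"] + annual["transp"] + annual["interception"]
        assert np.all(aet.to_numpy() <= annual["pet"].to_numpy())
        initial_storage = daily["storage"].iloc[0] + daily["transp"].iloc[0] \
            + daily["evap"].iloc[0] + daily["drainage"].iloc[0]
        assert aet.sum() <= daily["precip"].sum() + initial_storage

    def test_doubling_precip_never_decreases_transpiration(
            self, dryland_weather, profile, vegetation):
        rh, wind, cloud = self._atmos()
        base = simulate(dryland_weather, profile, vegetation, 40.0,
                        rh, wind, cloud)
        w2 = dryland_weather.copy()
        w2["precip"] = 2.0 * w2["precip"]
        doubled = simulate(w2, profile, vegetation, 40.0, rh, wind, cloud)
        assert doubled.daily["transp"].sum() >= base.daily["transp"].sum() - 1e-9

    def test_single_year_rejected(self, profile, vegetation):
        p = WeatherGenParams(mat_target=8, map_target=300, years=2, seed=0)
        w = gen_daily_weather(p)
        one_year = w[pd.DatetimeIndex(w["date"]).year == 2000]
        rh, wind, cloud = self._atmos()
        with pytest.raises(ValueError):
            simulate(one_year, profile, vegetation, 40.0, rh, wind, cloud)

    def test_closure_on_random_weather_and_soils(self):
        rng = np.random.default_rng(7)
        for k in range(3):
            params = WeatherGenParams(
                mat_target=rng.uniform(-2, 18), map_target=rng.uniform(80, 900),
                precip_seasonality=rng.uniform(0, 1), years=2,
                seed=int(rng.integers(1 << 30)))
            w = gen_daily_weather(params)
            prof = gen_soil_profile(rng.uniform(0.1, 0.7), rng.uniform(0.05, 0.25),
                                    rng.choice([60, 100, 150]))
            veg = build_vegetation(apply_monthly_normals(w), prof)
            res = simulate(w, prof, veg, 40.0, *self._atmos())
            assert np.abs(res.daily["residual"]).max() < 1e-6
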