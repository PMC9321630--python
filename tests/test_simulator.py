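"""Time-stepping driver, scenario engine and diagnostics."""

import numpy as np
import pandas as pd
import pytest

import profitmax as pm
from profitmax import constants as const
from profitmax.simulator import VPD_FLOOR_KPA, SimulationOutput, _leaf_environment


def _make_output(psi_series, plc=None, species="E. blakelyi"):
    data = pd.DataFrame(
        {
            "psi_leaf": psi_series,
            "psi_soil_w": psi_series,
            "PLC": 0.0 if plc is None else plc,
            "A": 0.0,
            "g_sw": 0.0,
            "E_leaf": 0.0,
            "E_canopy_mm": 0.0,
            "precip_mm": 0.0,
            "closed": False,
        },
        index=psi_series.index,
    )
    theta = pd.DataFrame(0.3, index=psi_series.index, columns=[f"layer_{i}" for i in range(6)])
    return SimulationOutput(data, theta, species, "abc", 0)


class TestRunSite:
    def test_single_step_matches_direct_optimiser_call(self, blakelyi, wet_soil, short_forcing):
        one = short_forcing.iloc[[36]]  # a midday step
        cfg = pm.RunConfig()
        out = pm.run_site(one, blakelyi, wet_soil, cfg, spin_up=False)
        psi_w, _ = pm.weighted_soil_potential(wet_soil)
        row = one.iloc[0]
        env = _leaf_environment(
            next(one.itertuples(index=False)), cfg.lai_for_month(one.index[0].month),
            cfg.co2_scale,
        )
        sol = pm.optimise_gas_exchange(
            env, psi_w, blakelyi, pm.OptimiserSettings(n_ci=cfg.n_ci)
        )
        assert out.data["psi_leaf"].iloc[0] == sol.psi_leaf
        assert out.data["A"].iloc[0] == sol.A
        assert out.data["g_sw"].iloc[0] == sol.g_sw

    def test_rainless_drought_dries_monotonically(self, blakelyi, short_forcing):
        soil = pm.default_profile(theta_frac=0.55)
        out = pm.run_site(short_forcing, blakelyi, soil, pm.RunConfig(), spin_up=False)
        psi_soil = out.data["psi_soil_w"]
        assert np.all(np.diff(psi_soil.values) <= 1e-9)
        assert out.data["PLC"].iloc[-8:].max() > out.data["PLC"].iloc[:8].max()
        # running minimum of psi_leaf is non-increasing by construction;
        # the drought must deepen it over the run
        assert out.data["psi_leaf"].iloc[-80:].min() < out.data["psi_leaf"].iloc[:80].min()

    def test_bitwise_determinism(self, blakelyi, short_forcing):
        soil = pm.default_profile(theta_frac=0.6)
        a = pm.run_site(short_forcing, blakelyi, soil, pm.RunConfig(), spin_up=False)
        b = pm.run_site(short_forcing, blakelyi, soil, pm.RunConfig(), spin_up=False)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.soil_theta, b.soil_theta)

    def test_nan_forcing_names_timestamp(self, blakelyi, wet_soil, short_forcing):
        bad = short_forcing.copy()
        bad.iloc[5, bad.columns.get_loc("T_air")] = np.nan
        with pytest.raises(ValueError, match=str(bad.index[5])):
            pm.run_site(bad, blakelyi, wet_soil, pm.RunConfig())

    def test_canopy_water_unit_roundtrip(self, blakelyi, short_forcing):
        """Soil extraction equals LAI-scaled leaf transpiration, mmol -> mm."""
        soil = pm.default_profile(theta_frac=0.8)
        cfg = pm.RunConfig(lai=1.5)
        out = pm.run_site(short_forcing.iloc[:80], blakelyi, soil, cfg, spin_up=False)
        expected = (
            out.data["E_leaf"] * 1.5 * cfg.timestep * const.MOLAR_MASS_WATER * 1e-6
        )
        # wet soil: no extraction shortfall, so the match is exact
        assert np.allclose(out.data["E_canopy_mm"].values, expected.values, atol=1e-12)

    def test_vpd_floor_applied(self):
        row = pd.DataFrame(
            {"SW_down": [500.0], "T_air": [15.0],
             "e_air": [pm.photosyn.saturation_vapour_pressure(15.0)],
             "precip": [0.0], "wind": [2.0], "P_atm": [101.325], "CO2": [400.0]},
        )
        env = _leaf_environment(next(row.itertuples(index=False)), 2.0, 1.0)
        assert env.VPD_leaf == VPD_FLOOR_KPA


class TestScenarios:
    def test_precipitation_scaling_exact(self, blakelyi, short_forcing):
        f = short_forcing.copy()
        f["precip"] = 0.5
        soil = pm.default_profile(theta_frac=0.6)
        outs = pm.run_scenarios(f.iloc[:16], blakelyi, soil, pm.RunConfig())
        assert outs["rPPT"].data["precip_mm"].sum() == pytest.approx(
            0.8 * outs["CTL"].data["precip_mm"].sum()
        )
        assert set(outs) == {"CTL", "rPPT", "eCO2_rPPT"}

    def test_sensitivity_suite_overrides(self, blakelyi, short_forcing):
        soil = pm.default_profile(theta_frac=0.6)
        outs = pm.sensitivity_suite(short_forcing.iloc[:16], blakelyi, soil, pm.RunConfig())
        assert set(outs) == {"kcrit_x2", "kmax_half", "eLAI", "eCO2_eLAI"}


class TestSummarise:
    def test_constant_series(self, blakelyi):
        idx = pd.date_range("2017-01-01", periods=12, freq="MS")
        out = _make_output(pd.Series(-1.0, index=idx))
        s = pm.summarise(out, blakelyi)
        assert s["psi_min"] == -1.0
        assert s["months_below_p50"] == 0

    def test_three_of_twelve_months_below_p50(self, blakelyi):
        idx = pd.date_range("2017-01-01", periods=12, freq="MS")
        psi = pd.Series(-1.0, index=idx)
        psi.iloc[:3] = blakelyi.P50 - 1.0
        s = pm.summarise(_make_output(psi), blakelyi)
        assert s["months_below_p50"] == 3
        assert s["fraction_months_below_p50"] == pytest.approx(0.25)

    def test_empty_output_rejected(self, blakelyi):
        idx = pd.date_range("2017-01-01", periods=0, freq="MS")
        with pytest.raises(ValueError):
            pm.summarise(_make_output(pd.Series(dtype=float, index=idx)), blakelyi)


class TestRangeSummary:
    @pytest.fixture
    def two_site_outputs(self):
        idx = pd.date_range("2017-01-01", periods=6, freq="MS")
        return {
            "E. blakelyi": {
                "s1": _make_output(pd.Series(-1.0, index=idx), plc=30.0),
                "s2": _make_output(pd.Series(-2.0, index=idx), plc=50.0),
            },
            "E. obliqua": {
                "s1": _make_output(pd.Series(-3.0, index=idx), plc=70.0),
            },
        }

    def test_single_species_everywhere(self, two_site_outputs, registry):
        outputs = {"E. blakelyi": two_site_outputs["E. blakelyi"]}
        presence = {"s1": ["E. blakelyi"], "s2": ["E. blakelyi"]}
        rs = pm.range_summary(outputs, presence, registry)
        assert rs.weighted_max_plc["s1"] == 30.0
        assert rs.weighted_max_plc["s2"] == 50.0
        assert rs.psi_min["E. blakelyi"].to_dict() == {"s1": -1.0, "s2": -2.0}

    def test_two_species_equal_weighting(self, two_site_outputs, registry):
        presence = {"s1": ["E. blakelyi", "E. obliqua"], "s2": ["E. blakelyi"]}
        rs = pm.range_summary(two_site_outputs, presence, registry)
        assert rs.weighted_max_plc["s1"] == pytest.approx((30.0 + 70.0) / 2)

    def test_all_sites_above_p50_gives_zero_proportion(self, two_site_outputs, registry):
        presence = {"s1": ["E. blakelyi"], "s2": ["E. blakelyi"]}
        rs = pm.range_summary(
            {"E. blakelyi": two_site_outputs["E. blakelyi"]}, presence, registry
        )
        assert rs.proportion_below_p50["E. blakelyi"] == 0.0

    def test_absent_species_excluded_with_warning(self, two_site_outputs, registry):
        presence = {"s1": ["E. blakelyi"], "s2": ["E. blakelyi"]}
        with pytest.warns(UserWarning, match="obliqua"):
            rs = pm.range_summary(two_site_outputs, presence, registry)
        assert "E. obliqua" not in rs.psi_min


class TestOutputContainer:
    def test_netcdf_roundtrip(self, blakelyi, wet_soil, short_forcing, tmp_path):
        out = pm.run_site(
            short_forcing.iloc[:8], blakelyi, wet_soil, pm.RunConfig(), spin_up=False
        )
        path = tmp_path / "run.nc"
        out.to_netcdf(path)
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        assert ds.sizes["time"] == 8 and ds.sizes["layer"] == 6
        np.testing.assert_allclose(ds["psi_leaf"].values, out.data["psi_leaf"].values)
        ds.close()
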