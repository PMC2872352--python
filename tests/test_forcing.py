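"""Forcing parsers, synthetic generator contract, and output round trips."""

import numpy as np
import pandas as pd
import pytest

import lagoonfate as lf
from lagoonfate.errors import ForcingParseError, UnitError
from lagoonfate.forcing import parse_concentration, write_forcing_csv

from conftest import make_constant_forcing


class TestConcentrationParser:
    @pytest.mark.parametrize("text,expected", [
        ("3.00·10−6", 3.00e-6),
        ("3.00e-6", 3.00e-6),
        ("4 10−3", 4e-3),
        ("54,784", 54784.0),
        ("75.99", 75.99),
        ("5.7·10−2", 5.7e-2),
    ])
    def test_dialects(self, text, expected):
        assert parse_concentration(text) == pytest.approx(expected, rel=1e-12)

    def test_garbage_rejected(self):
        with pytest.raises(ForcingParseError):
            parse_concentration("not-a-number")


class TestBoundaryTable:
    def test_packaged_values(self, boundary):
        assert boundary.loc["OCDD", "rain"] == pytest.approx(75.99)
        assert boundary.loc["PeCDD", "sediment"] == pytest.approx(256.0)
        assert boundary.loc["OCDD", "river"] == pytest.approx(1842.0)
        assert boundary.loc["HxCDF", "open_sea"] == pytest.approx(4e-3)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises((ForcingParseError, Exception)):
            lf.read_boundary_concentrations(p)

    def test_negative_value_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("congener\tgas\tair_particulate\train\tsediment\triver\topen_sea\n"
                     "X\t-1\t0\t0\t0\t0\t0\n")
        with pytest.raises(ForcingParseError, match="gas"):
            lf.read_boundary_concentrations(p)


class TestSyntheticForcing:
    def test_determinism(self):
        a = lf.generate_synthetic_forcing(seed=1, days=30)
        b = lf.generate_synthetic_forcing(seed=1, days=30)
        assert np.array_equal(a.time, b.time)
        assert a.met.equals(b.met)
        for k in a.river_discharge:
            assert np.array_equal(a.river_discharge[k], b.river_discharge[k])

    def test_annual_rain_total_exact(self):
        frc = lf.generate_synthetic_forcing(seed=3, days=365, step=600.0,
                                            annual_rain_mm=500.0)
        total_mm = frc.met["rain_rate"].sum() * frc.step * 1000.0
        assert total_mm == pytest.approx(500.0, rel=1e-6)

    def test_temperature_bands(self):
        """Default seasonal cycle spans the observed 5-29 degC range."""
        frc = lf.generate_synthetic_forcing(seed=1, days=365, step=600.0)
        for col in ("T_air", "T_water"):
            t = frc.met[col] - 273.15
            assert 4.0 <= t.min() <= 6.0, col
            assert 28.0 <= t.max() <= 30.0, col

    def test_rain_stability_across_seeds(self):
        totals = []
        for seed in range(20):
            frc = lf.generate_synthetic_forcing(seed=seed, days=60, step=3600.0)
            totals.append(frc.met["rain_rate"].sum() * 3600.0 * 1000.0)
        target = 102.0 * 60 / 365
        assert abs(np.mean(totals) - target) / target < 0.15

    def test_salinity_and_wind_plausible(self):
        frc = lf.generate_synthetic_forcing(seed=2, days=365, step=3600.0)
        s = frc.met["salinity"]
        assert 26.0 < s.min() < 28.0 and 39.0 < s.max() < 41.0
        assert 3.0 < frc.met["u10"].mean() < 8.0


class TestForcingIO:
    def test_csv_round_trip_and_interpolation(self, tmp_path):
        frc = make_constant_forcing(days=2, step=43200.0, u10=3.0,
                                    discharge={"riv_west": 0.5})
        # hand-edit a two-point wind ramp for the interpolation check
        frc.met.loc[:, "u10"] = np.linspace(0.0, 10.0, len(frc.time))
        p = tmp_path / "forcing.csv"
        write_forcing_csv(frc, p)
        rd = lf.read_forcing(p, step=600.0)
        # sample at mid-ramp: linear interpolation
        i = np.searchsorted(rd.time, frc.time[-1] / 2.0)
        assert rd.met["u10"].iloc[i] == pytest.approx(5.0, abs=0.05)
        assert rd.river_discharge["riv_west"][0] == pytest.approx(0.5)

    def test_constant_column_stays_constant(self, tmp_path):
        frc = make_constant_forcing(days=1, step=21600.0, t_water=290.15)
        p = tmp_path / "forcing.csv"
        write_forcing_csv(frc, p)
        rd = lf.read_forcing(p, step=600.0)
        assert np.allclose(rd.met["T_water"], 290.15)

    def test_interpolation_conserves_interval_mean(self, tmp_path):
        """Refining a coarse series by linear interpolation preserves the
        trapezoid mean over each coarse interval to round-off."""
        frc = make_constant_forcing(days=2, step=86400.0,
                                    discharge={"riv_west": 1.0})
        q = np.array([2.0, 6.0, 4.0])
        frc.river_discharge["riv_west"] = q
        p = tmp_path / "forcing.csv"
        write_forcing_csv(frc, p)
        rd = lf.read_forcing(p, step=600.0)
        fine = rd.river_discharge["riv_west"]
        day = 144  # 600 s steps per day
        mean_day1 = np.trapezoid(fine[:day + 1], dx=600.0) / 86400.0
        assert mean_day1 == pytest.approx((q[0] + q[1]) / 2.0, rel=1e-12)

    def test_unit_mismatch_rejected(self, tmp_path):
        frc = make_constant_forcing(days=1, step=43200.0)
        p = tmp_path / "forcing.csv"
        write_forcing_csv(frc, p)
        text = p.read_text().replace("m s-1", "knots", 1)
        p.write_text(text)
        with pytest.raises(UnitError):
            lf.read_forcing(p, step=600.0)

    def test_non_monotone_time_rejected(self, tmp_path):
        p = tmp_path / "forcing.csv"
        cols = "time,T_air,u10,rain_rate,cloud,rh,T_water,salinity,irradiance"
        units = "#units,K,m s-1,m s-1,1,1,K,PSS78,W m-2"
        rows = ["0,280,5,0,0.3,0.7,285,35,100",
                "600,280,5,0,0.3,0.7,285,35,100",
                "300,280,5,0,0.3,0.7,285,35,100"]
        p.write_text("\n".join([cols, units] + rows) + "\n")
        with pytest.raises(ForcingParseError):
            lf.read_forcing(p, step=600.0)


class TestOutputRoundTrip:
    def test_netcdf_round_trip_bitwise(self, tmp_path, year_run):
        ds = year_run.to_dataset().isel(time=slice(0, 10))
        p = tmp_path / "out.nc"
        lf.write_outputs(ds, p)
        back = lf.read_outputs(p)
        for var in ("flux_mass", "water_conc", "sediment_conc"):
            assert np.array_equal(back[var].values, ds[var].values), var
        assert back["water_conc"].attrs["units"] == "ng m-3"
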