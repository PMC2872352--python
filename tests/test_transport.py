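"""Box transport: analytic oracles, conservation and the mass ledger."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import lagoonfate as lf
from lagoonfate.errors import ConfigError
from lagoonfate.transport import BOUNDARY_PROCESSES

from conftest import make_constant_forcing, zero_boundary


def two_box_geometry(volume=1e6, q=1.0):
    boxes = [lf.Box("a", volume, 1e4, 1e4, volume / 1e4),
             lf.Box("b", volume, 1e4, 1e4, volume / 1e4)]
    return lf.LagoonGeometry(boxes=boxes, connections=[("a", "b", q)])


class TestTendencies:
    def test_uniform_field_is_fixed_point(self):
        geo = lf.default_thau_geometry()
        conc = np.full((3, 2), 0.7)
        dcdt = lf.transport_tendencies(conc, geo, {"riv_west": 1.0, "riv_centre": 1.0},
                                       river_conc=np.full(2, 0.7),
                                       sea_conc=np.full(2, 0.7))
        assert np.allclose(dcdt, 0.0, atol=1e-18)

    def test_unknown_box_rejected(self):
        boxes = [lf.Box("a", 1e6, 1e4, 1e4, 100.0)]
        with pytest.raises(ConfigError):
            lf.LagoonGeometry(boxes=boxes, connections=[("a", "ghost", 1.0)])

    def test_two_box_mixing_matches_analytic_exponential(self):
        """Concentration difference decays as exp(-2Qt/V) in an isolated
        equal-volume pair; integrated tendencies match within 1e-6."""
        V, q = 1e6, 1.0
        geo = two_box_geometry(V, q)
        c0 = np.array([[1.0], [0.0]])

        def rhs(t, y):
            return lf.transport_tendencies(y.reshape(2, 1), geo, {},
                                           np.zeros(1), np.zeros(1)).ravel()

        t_end = V / q  # 2 e-foldings of the difference mode
        sol = solve_ivp(rhs, (0.0, t_end), c0.ravel(), rtol=1e-11, atol=1e-14)
        diff = sol.y[0, -1] - sol.y[1, -1]
        expect = np.exp(-2.0 * q * t_end / V)
        assert diff == pytest.approx(expect, rel=1e-6)
        # total mass invariant under pure mixing
        assert sol.y[:, -1].sum() == pytest.approx(1.0, rel=1e-9)

    def test_single_box_sea_flushing(self):
        """Exchange with clean sea water: pure exponential exp(-Qt/V)."""
        V, q = 1e6, 2.0
        geo = lf.LagoonGeometry(boxes=[lf.Box("a", V, 1e4, 1e4, 100.0)],
                                sea_links=[("a", q)])

        def rhs(t, y):
            return lf.transport_tendencies(y.reshape(1, 1), geo, {},
                                           np.zeros(1), np.zeros(1)).ravel()

        t_end = 3.0 * V / q
        sol = solve_ivp(rhs, (0.0, t_end), [1.0], rtol=1e-11, atol=1e-14)
        assert sol.y[0, -1] == pytest.approx(np.exp(-3.0), rel=1e-6)


class TestSimulationConservation:
    def test_closed_system_conserves_mass(self, congener_table):
        """No boundary fluxes, no degradation: total (water + sediment)
        mass per congener constant to 1e-9 relative over 1e4 steps."""
        names = congener_table.names
        frc = make_constant_forcing(days=70, step=600.0, u10=0.0,
                                    rain_rate=0.0,
                                    boundary=zero_boundary(names))
        geo = two_box_geometry(volume=4e4, q=0.05)
        params = lf.ProcessParams(gamma_sed=0.0, w_burial=0.0)
        sim = lf.Simulation(geometry=geo, forcing=frc, params=params,
                            dt=600.0, ecology_on=False,
                            initial_conc=np.full((2, len(names)), 1.0),
                            initial_sediment=np.full((2, len(names)), 10.0))
        res = sim.run()
        n_steps = 70 * 144
        assert n_steps >= 1e4
        assert float(res.ledger.residual().max()) < 1e-9
        # every boundary process is identically zero
        for p in BOUNDARY_PROCESSES:
            assert np.all(res.ledger.cumulative[p] == 0.0), p
        assert np.allclose(res.ledger.inventory, res.ledger.initial, rtol=1e-9)

    def test_no_negative_concentrations_with_strong_exchange(self, congener_table):
        frc = make_constant_forcing(days=5, step=600.0, u10=15.0)
        geo = lf.LagoonGeometry(
            boxes=[lf.Box("a", 2e5, 1e5, 1e5, 2.0)],
            sea_links=[("a", 5.0)])
        sim = lf.Simulation(geometry=geo, forcing=frc, dt=600.0,
                            ecology_on=False)
        res = sim.run()
        assert np.all(res.water_conc >= 0.0)
        assert np.all(res.sediment_conc >= 0.0)

    def test_randomized_run_ledger(self, congener_table):
        """30-day synthetic-forcing run on the Thau layout closes the
        mass ledger to 1e-6 relative."""
        frc = lf.generate_synthetic_forcing(seed=42, days=30, step=600.0)
        res = lf.Simulation(forcing=frc, dt=600.0).run()
        ok, resid = lf.mass_ledger_check(res.ledger, tol=1e-6)
        assert ok and float(resid.max()) < 1e-6


class TestSteadyState:
    def test_single_box_steady_state_matches_analytic_balance(self, congener_table):
        """With constant forcing, frozen sediment and fixed organic carbon,
        the long-run concentration equals inputs / first-order losses."""
        names = congener_table.names
        bnd = lf.read_boundary_concentrations()
        rain_rate = 0.102 / lf.SECONDS_PER_YEAR
        u10, tw = 5.0, 288.15
        frc = make_constant_forcing(days=150, step=600.0, u10=u10,
                                    t_water=tw, rain_rate=rain_rate,
                                    boundary=bnd)
        V, A, depth = 2e7 * 2.0, 2e7, 2.0
        q_sea = 80.0
        geo = lf.LagoonGeometry(boxes=[lf.Box("a", V, A, A, depth)],
                                sea_links=[("a", q_sea)])
        poc, doc = 3e-4, 1e-3
        params = lf.ProcessParams()
        sim = lf.Simulation(geometry=geo, forcing=frc, params=params,
                            dt=600.0, ecology_on=False, sediment_dynamic=False,
                            fixed_poc=poc, fixed_doc=doc)
        res = sim.run()
        simulated = res.water_conc[-1, 0, :]

        # independent balance from the same constants
        kow = lf.temperature_correct(10.0 ** congener_table.array("log_kow_25"),
                                     congener_table.array("dU_ow"), tw)
        koc = 10.0 ** (np.log10(kow) - 0.21) * 1e-3
        kdoc = 0.08 * kow * 1e-3
        f_diss = 1.0 / (1.0 + koc * poc + kdoc * doc)
        f_part = koc * poc * f_diss
        h_prime = lf.dimensionless_henry(
            lf.temperature_correct(congener_table.array("henry_25"),
                                   congener_table.array("dU_aw"), tw), tw)
        k_ol = lf.overall_transfer_velocity(u10, h_prime, tw,
                                            congener_table.array("molar_mass"))
        c_surf = bnd["sediment"].to_numpy() / params.bulk_dry_density
        c_pore = c_surf / (koc * params.f_oc_sed)
        inputs = ((k_ol * bnd["gas"].to_numpy() / h_prime
                   + params.v_d * bnd["air_particulate"].to_numpy()
                   + rain_rate * bnd["rain"].to_numpy()
                   + params.k_sw * c_pore
                   + params.r_s * c_surf) / depth
                  + q_sea * bnd["open_sea"].to_numpy() / V)
        losses = ((k_ol * f_diss + params.w_s * f_part
                   + params.k_sw * f_diss) / depth + q_sea / V)
        assert simulated == pytest.approx(inputs / losses, rel=1e-3)
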