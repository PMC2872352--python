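import numpy as np
import pandas as pd
import pytest

import lagoonfate as lf
from lagoonfate.forcing import MET_COLUMNS, ForcingSeries


@pytest.fixture(scope="session")
def congener_table():
    return lf.CongenerTable.from_tsv()


@pytest.fixture(scope="session")
def boundary():
    return lf.read_boundary_concentrations()


@pytest.fixture(scope="session")
def year_run():
    """One full synthetic year on the default three-box Thau layout."""
    frc = lf.generate_synthetic_forcing(seed=42, days=365, step=600.0)
    sim = lf.Simulation(forcing=frc, dt=600.0)
    return sim.run()


def make_constant_forcing(days, step=600.0, u10=5.0, t_water=288.15,
                          t_air=288.15, rain_rate=0.0, irradiance=100.0,
                          boundary=None, discharge=None):
    """Constant-in-time forcing series for analytic scenarios."""
    n = int(round(days * 86400.0 / step)) + 1
    time = np.arange(n) * step
    met = pd.DataFrame({c: np.full(n, v) for c, v in {
        "T_air": t_air, "u10": u10, "rain_rate": rain_rate, "cloud": 0.3,
        "rh": 0.7, "T_water": t_water, "salinity": 35.0,
        "irradiance": irradiance,
    }.items()}, index=time)[list(MET_COLUMNS)]
    if boundary is None:
        boundary = lf.read_boundary_concentrations()
    riv = {} if discharge is None else {
        k: np.full(n, q) for k, q in discharge.items()}
    return ForcingSeries(time=time, met=met, river_discharge=riv,
                         boundary=boundary)


def zero_boundary(names):
    """Boundary table with all compartments at zero for the given congeners."""
    cols = ["gas", "air_particulate", "rain", "sediment", "river", "open_sea"]
    return pd.DataFrame(0.0, index=list(names), columns=cols)
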