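"""Forcing I/O and the synthetic Thau-like forcing generator.

A :class:`ForcingSeries` bundles, on one strictly increasing regular time
grid: meteorology (air temperature, wind at 10 m, rain rate, cloud and
relative-humidity fractions, daily-mean irradiance), per-box water
temperature and salinity, river discharge per river link, and the constant
per-congener boundary concentrations (gas, air particulate, rain, deep
sediment, river, open sea).

The synthetic generator emulates one Thau-like year: seasonal temperatures
spanning about 5-29 degC, Weibull wind, Poisson-arrival rain events with
gamma-distributed depths renormalized to a configured annual total, and
rain-driven river runoff from a small catchment.  Identical seeds give
bit-identical series.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ForcingParseError, InvalidInputError, UnitError

MET_COLUMNS = ("T_air", "u10", "rain_rate", "cloud", "rh",
               "T_water", "salinity", "irradiance")

EXPECTED_UNITS = {
    "time": "s",
    "T_air": "K",
    "u10": "m s-1",
    "rain_rate": "m s-1",
    "cloud": "1",
    "rh": "1",
    "T_water": "K",
    "salinity": "PSS78",
    "irradiance": "W m-2",
    "discharge": "m3 s-1",
}

BOUNDARY_COMPARTMENTS = ("gas", "air_particulate", "rain",
                         "sediment", "river", "open_sea")

_NUMBER_RE = re.compile(
    r"^\s*([0-9]*\.?[0-9]+)\s*(?:[·x×*]\s*10|\s+10|[eE])\s*\^?\s*([+-−]?[0-9]+)\s*\^?\s*$")


def parse_concentration(text) -> float:
    """Parse a concentration in the dialects of the source tables.

    Accepts plain floats, ``3.00e-6``, ``3.00·10−6`` (middle dot, unicode
    minus), ``4 10−3`` and values with thousands separators (``54,784``).
    """
    s = str(text).strip().replace(",", "").replace("−", "-")
    if not s:
        raise ForcingParseError("empty concentration field")
    m = _NUMBER_RE.match(s)
    if m:
        return float(m.group(1)) * 10.0 ** int(m.group(2).replace("−", "-"))
    try:
        return float(s)
    except ValueError:
        raise ForcingParseError(f"cannot parse concentration {text!r}") from None


@dataclass
class ForcingSeries:
    """Time-stamped model forcing on a regular grid.

    ``time`` holds seconds since the run start (1 January by convention);
    ``met`` is a DataFrame with :data:`MET_COLUMNS`; ``river_discharge``
    maps river-link series ids to discharge arrays (m3 s-1); ``boundary``
    is a congener-by-compartment DataFrame in ng m-3.
    """

    time: np.ndarray
    met: pd.DataFrame
    river_discharge: dict[str, np.ndarray]
    boundary: pd.DataFrame
    start: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2005-01-01"))

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise InvalidInputError("ForcingSeries: need at least two time points")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidInputError("ForcingSeries: time must be strictly increasing")
        if len(self.met) != len(self.time):
            raise InvalidInputError("ForcingSeries: met length mismatch")
        if self.met.isna().any().any():
            raise InvalidInputError("ForcingSeries: missing values in met series")
        if np.any(self.met["rain_rate"].to_numpy() < 0):
            raise InvalidInputError("ForcingSeries: rain_rate must be >= 0")
        for name, q in self.river_discharge.items():
            if np.any(np.asarray(q) < 0):
                raise InvalidInputError(f"ForcingSeries: discharge {name} must be >= 0")

    @property
    def step(self) -> float:
        return float(self.time[1] - self.time[0])

    def interp_met(self, times: np.ndarray) -> pd.DataFrame:
        """Linear interpolation of all met columns onto a new grid."""
        out = {c: np.interp(times, self.time, self.met[c].to_numpy())
               for c in self.met.columns}
        return pd.DataFrame(out, index=times)

    def interp_discharge(self, times: np.ndarray) -> dict[str, np.ndarray]:
        return {k: np.interp(times, self.time, np.asarray(v, dtype=float))
                for k, v in self.river_discharge.items()}


def read_boundary_concentrations(path=None) -> pd.DataFrame:
    """Read a per-congener boundary concentration table (ng m-3).

    Defaults to the packaged Thau table.  Requires the six compartment
    columns; raises :class:`ForcingParseError` naming the offending
    row/column on negative or unparsable values.
    """
    if path is None:
        path = resources.files("lagoonfate.data") / "boundary_concentrations.tsv"
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if raw.empty or "congener" not in raw.columns:
        raise ForcingParseError(f"{path}: empty or missing 'congener' column")
    missing = set(BOUNDARY_COMPARTMENTS) - set(raw.columns)
    if missing:
        raise ForcingParseError(f"{path}: missing compartments {sorted(missing)}")
    out = {}
    for _, row in raw.iterrows():
        name = str(row["congener"]).strip()
        vals = {}
        for comp in BOUNDARY_COMPARTMENTS:
            try:
                v = parse_concentration(row[comp])
            except ForcingParseError as exc:
                raise ForcingParseError(f"row {name!r}, column {comp!r}: {exc}") from None
            if v < 0:
                raise ForcingParseError(f"row {name!r}, column {comp!r}: negative value")
            vals[comp] = v
        out[name] = vals
    return pd.DataFrame.from_dict(out, orient="index")[list(BOUNDARY_COMPARTMENTS)]


def read_forcing(path, step: float, boundary: pd.DataFrame | None = None) -> ForcingSeries:
    """Read meteorological/hydrological forcing from CSV (or NetCDF) onto a grid.

    CSV layout: header row, then a unit row whose first cell is ``#units``;
    columns ``time`` plus any of :data:`MET_COLUMNS` and ``discharge_<id>``
    river series.  Units are validated against :data:`EXPECTED_UNITS`
    (a declared-unit check, not a heuristic).  Series are linearly
    interpolated onto the regular ``step`` grid spanning the file.
    """
    path = str(path)
    if path.endswith(".nc"):
        ds = xr.open_dataset(path, engine="scipy")
        time = np.asarray(ds["time"].values, dtype=float)
        columns = {v: np.asarray(ds[v].values, dtype=float) for v in ds.data_vars}
        units = {v: ds[v].attrs.get("units", "") for v in ds.data_vars}
        ds.close()
    else:
        raw = pd.read_csv(path, dtype=str)
        if raw.empty or "time" not in raw.columns:
            raise ForcingParseError(f"{path}: empty file or missing 'time' column")
        if str(raw.iloc[0]["time"]).strip() != "#units":
            raise ForcingParseError(f"{path}: second row must be the unit row "
                                    "('#units' in the time column)")
        units = {c: str(raw.iloc[0][c]).strip() for c in raw.columns if c != "time"}
        data = raw.iloc[1:].astype(float)
        time = data["time"].to_numpy()
        columns = {c: data[c].to_numpy() for c in data.columns if c != "time"}
    if np.any(np.diff(time) <= 0):
        raise ForcingParseError(f"{path}: non-monotone time column")
    for name, unit in units.items():
        key = "discharge" if name.startswith("discharge") else name
        expected = EXPECTED_UNITS.get(key)
        if expected is not None and unit != expected:
            raise UnitError(f"{path}: column {name!r} declared unit {unit!r}, "
                            f"expected {expected!r}")
    grid = np.arange(time[0], time[-1] + 0.5 * step, step)
    met = {}
    for c in MET_COLUMNS:
        if c not in columns:
            raise ForcingParseError(f"{path}: missing forcing column {c!r}")
        met[c] = np.interp(grid, time, columns[c])
    discharge = {name.split("discharge_", 1)[1]: np.interp(grid, time, arr)
                 for name, arr in columns.items() if name.startswith("discharge_")}
    if boundary is None:
        boundary = read_boundary_concentrations()
    return ForcingSeries(time=grid, met=pd.DataFrame(met, index=grid),
                         river_discharge=discharge, boundary=boundary)


def write_forcing_csv(forcing: ForcingSeries, path) -> None:
    """Write a ForcingSeries as CSV with the declared-unit row."""
    df = forcing.met.copy()
    for k, v in forcing.river_discharge.items():
        df[f"discharge_{k}"] = v
    df.insert(0, "time", forcing.time)
    units = [EXPECTED_UNITS["discharge" if c.startswith("discharge") else c]
             for c in df.columns if c != "time"]
    with open(path, "w") as fh:
        fh.write(",".join(df.columns) + "\n")
        fh.write(",".join(["#units"] + units) + "\n")
        df.to_csv(fh, index=False, header=False)


def generate_synthetic_forcing(seed: int, days: int = 365, step: float = 600.0,
                               annual_rain_mm: float = 102.0,
                               river_ids: tuple[str, ...] = ("riv_west", "riv_centre"),
                               catchment_km2: float = 280.0,
                               runoff_coefficient: float = 0.2,
                               boundary: pd.DataFrame | None = None) -> ForcingSeries:
    """Generate one reproducible Thau-like forcing year.

    * air/water temperature: seasonal sinusoid, minimum ~5 degC in February
      and maximum ~29 degC in August (small AR(1) noise on air only);
    * rain: Poisson event arrivals (~40 yr-1), gamma depths renormalized so
      the annual total equals ``annual_rain_mm`` exactly;
    * wind: Weibull (shape 2, scale 6.2 m s-1) per 3-hour block;
    * river discharge: baseflow plus rain-driven runoff from
      ``catchment_km2`` with a 2-day exponential recession, split evenly
      across ``river_ids``;
    * boundary concentrations: constant, from the packaged Thau table.
    """
    if days < 1:
        raise InvalidInputError("generate_synthetic_forcing: days must be >= 1")
    if not 100.0 <= annual_rain_mm <= 1000.0:
        raise InvalidInputError("annual_rain_mm must lie in [100, 1000]")
    rng = np.random.default_rng(seed)
    n = int(round(days * 86400.0 / step)) + 1
    time = np.arange(n) * step
    doy = time / 86400.0 % 365.0

    t_air = 17.0 + 12.0 * np.cos(2.0 * np.pi * (doy - 220.0) / 365.0)
    noise = np.empty(n)
    noise[0] = 0.0
    eps = rng.normal(0.0, 0.025, size=n)
    rho = 0.99
    for i in range(1, n):
        noise[i] = rho * noise[i - 1] + eps[i]
    t_air = t_air + noise
    t_water = 17.0 + 12.0 * np.cos(2.0 * np.pi * (doy - 230.0) / 365.0)
    salinity = 33.5 + 6.5 * np.cos(2.0 * np.pi * (doy - 220.0) / 365.0)

    # Poisson rain events, ~6 h duration, gamma depths, exact annual total
    rain = np.zeros(n)
    n_events = rng.poisson(40.0 * days / 365.0)
    if n_events > 0:
        starts = rng.integers(0, n - 1, size=n_events)
        depths = rng.gamma(shape=1.2, scale=1.0, size=n_events)
        depths *= (annual_rain_mm * 1.0e-3 * days / 365.0) / depths.sum()
        dur_steps = np.maximum(1, np.round(rng.exponential(6.0 * 3600.0 / step,
                                                           size=n_events)).astype(int))
        for s, d, ds in zip(starts, depths, dur_steps):
            e = min(n, s + ds)
            rain[s:e] += d / ((e - s) * step)
        total = rain.sum() * step
        rain *= (annual_rain_mm * 1.0e-3 * days / 365.0) / total
    cloud = np.clip(rng.beta(2.0, 3.0, size=n) + 0.5 * (rain > 0), 0.0, 1.0)
    rh = np.clip(0.7 + 0.1 * rng.standard_normal(n), 0.3, 1.0)

    block = max(1, int(round(3.0 * 3600.0 / step)))
    n_blocks = n // block + 1
    wind_blocks = rng.weibull(2.0, size=n_blocks) * 6.2
    u10 = np.repeat(wind_blocks, block)[:n]

    irradiance = (140.0 + 110.0 * np.cos(2.0 * np.pi * (doy - 172.0) / 365.0)) \
        * (1.0 - 0.6 * cloud)

    # rain-driven runoff with exponential recession (intermittent streams)
    runoff_in = rain * catchment_km2 * 1.0e6 * runoff_coefficient  # m3/s equivalent
    tau = 2.0 * 86400.0
    decay = np.exp(-step / tau)
    runoff = np.empty(n)
    runoff[0] = 0.0
    for i in range(1, n):
        runoff[i] = runoff[i - 1] * decay + runoff_in[i] * (1.0 - decay)
    baseflow = 0.05
    q_total = baseflow + runoff
    discharge = {rid: q_total / len(river_ids) for rid in river_ids}

    met = pd.DataFrame({
        "T_air": t_air + 273.15,
        "u10": u10,
        "rain_rate": rain,
        "cloud": cloud,
        "rh": rh,
        "T_water": t_water + 273.15,
        "salinity": salinity,
        "irradiance": irradiance,
    }, index=time)
    if boundary is None:
        boundary = read_boundary_concentrations()
    return ForcingSeries(time=time, met=met, river_discharge=discharge,
                         boundary=boundary)


def write_outputs(dataset: xr.Dataset, path) -> None:
    """Write a results dataset to NetCDF (classic format) with units kept."""
    dataset.to_netcdf(path, engine="scipy")


def read_outputs(path) -> xr.Dataset:
    """Read back a results dataset written by :func:`write_outputs`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()
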