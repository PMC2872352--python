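"""Physicochemical properties of the modelled PCDD/F congener groups.

The model tracks five groups, labelled by chlorination degree: PeCDD, OCDD,
TCDF, PeCDF and HxCDF.  Groups that assemble several 2,3,7,8-substituted
isomers (PeCDF, HxCDF) carry the arithmetic mean of the member properties,
since boundary concentrations are reported as the sum over members.

All partitioning and exchange parameterizations derive from three primary
constants per group: the octanol-water partition coefficient (log Kow), the
Henry's law constant H (Pa m3 mol-1) and the phase-transfer internal
energies used for van't Hoff temperature corrections.  The shipped default
values are literature stand-ins (see docs/methods.md) and every one of them
can be overridden through a user property table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidInputError

R_GAS = 8.314
"""Universal gas constant, J mol-1 K-1."""

T_REF = 298.15
"""Reference temperature for all tabulated properties, K."""

SECONDS_PER_YEAR = 3.1536e7
"""Fixed 365-day year used for every annualization, s."""

DEFAULT_SCAVENGING_RATIO = 2.0e5
"""Dimensionless rain particle scavenging ratio W_p."""


@dataclass(frozen=True)
class CongenerProperties:
    """Physicochemical constants of one congener group.

    Parameters
    ----------
    name
        Group label (chlorination degree), e.g. ``"PeCDF"``.
    members
        Isomer labels assembled under this group.
    molar_mass
        g mol-1.
    log_kow_25
        log10 octanol-water partition coefficient at 298.15 K.
    henry_25
        Henry's law constant at 298.15 K, Pa m3 mol-1.
    dU_aw, dU_ow
        Air-water and octanol-water phase-transfer internal energies,
        J mol-1, for van't Hoff temperature corrections.
    deg_rate_water, deg_rate_sediment
        First-order degradation rate constants, s-1.  Default 0 (persistent).
    """

    name: str
    members: tuple[str, ...]
    molar_mass: float
    log_kow_25: float
    henry_25: float
    dU_aw: float
    dU_ow: float
    deg_rate_water: float = 0.0
    deg_rate_sediment: float = 0.0

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise InvalidInputError(f"{self.name}: molar_mass must be > 0")
        if self.henry_25 <= 0:
            raise InvalidInputError(f"{self.name}: henry_25 must be > 0")
        if self.deg_rate_water < 0 or self.deg_rate_sediment < 0:
            raise InvalidInputError(f"{self.name}: degradation rates must be >= 0")


class CongenerTable:
    """Ordered collection of :class:`CongenerProperties` with array views."""

    def __init__(self, congeners: list[CongenerProperties]):
        if not congeners:
            raise InvalidInputError("empty congener table")
        names = [c.name for c in congeners]
        if len(set(names)) != len(names):
            raise InvalidInputError("duplicate congener labels in table")
        self._congeners = list(congeners)
        self._index = {c.name: i for i, c in enumerate(congeners)}

    @classmethod
    def from_tsv(cls, path=None) -> "CongenerTable":
        """Load a property table; defaults to the packaged stand-in values.

        Expected TSV header:
        ``name members molar_mass log_kow_25 henry_25 dU_aw dU_ow deg_w deg_s``
        with members comma-separated.
        """
        if path is None:
            path = resources.files("lagoonfate.data") / "congener_properties.tsv"
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"name", "members", "molar_mass", "log_kow_25", "henry_25",
                    "dU_aw", "dU_ow", "deg_w", "deg_s"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(f"property table missing columns: {sorted(missing)}")
        rows = [
            CongenerProperties(
                name=str(r["name"]),
                members=tuple(str(r["members"]).split(",")),
                molar_mass=float(r["molar_mass"]),
                log_kow_25=float(r["log_kow_25"]),
                henry_25=float(r["henry_25"]),
                dU_aw=float(r["dU_aw"]),
                dU_ow=float(r["dU_ow"]),
                deg_rate_water=float(r["deg_w"]),
                deg_rate_sediment=float(r["deg_s"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(rows)

    def __len__(self) -> int:
        return len(self._congeners)

    def __iter__(self):
        return iter(self._congeners)

    def __getitem__(self, name: str) -> CongenerProperties:
        try:
            return self._congeners[self._index[name]]
        except KeyError:
            raise KeyError(f"unknown congener label {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def names(self) -> list[str]:
        return [c.name for c in self._congeners]

    def array(self, attr: str) -> np.ndarray:
        """Return one property as a float array in table order."""
        return np.array([getattr(c, attr) for c in self._congeners], dtype=float)


def temperature_correct(value_25, dU, T):
    """Van't Hoff correction of a property from 298.15 K to temperature ``T``.

    ``value(T) = value_25 * exp(-(dU/R) * (1/T - 1/298.15))``

    A positive internal energy ``dU`` makes the property increase with
    temperature (as for Henry's law constants of hydrophobic organics).

    Raises
    ------
    InvalidInputError
        If ``value_25 <= 0`` or ``T`` outside [270, 320] K.
    """
    value_25 = np.asarray(value_25, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(value_25 <= 0):
        raise InvalidInputError("temperature_correct: value_25 must be > 0")
    if np.any((T < 270.0) | (T > 320.0)):
        raise InvalidInputError("temperature_correct: T outside [270, 320] K")
    out = value_25 * np.exp(-(np.asarray(dU, dtype=float) / R_GAS) * (1.0 / T - 1.0 / T_REF))
    return float(out) if out.ndim == 0 else out


def dimensionless_henry(H, T):
    """Dimensionless Henry constant H' = H / (R T) (gas/water concentration ratio)."""
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(H < 0):
        raise InvalidInputError("dimensionless_henry: H must be >= 0")
    if np.any(T <= 0):
        raise InvalidInputError("dimensionless_henry: T must be > 0")
    out = H / (R_GAS * T)
    return float(out) if out.ndim == 0 else out


def koc_from_kow(log_kow):
    """Organic-carbon partition coefficient from log Kow (Karickhoff regression).

    ``log10(Koc [L/kg]) = log_kow - 0.21``; returned in m3 per kg organic
    carbon.  Outside the calibration range [3, 9] a warning is emitted and
    the extrapolation proceeds.
    """
    log_kow = np.asarray(log_kow, dtype=float)
    if np.any((log_kow < 3.0) | (log_kow > 9.0)):
        warnings.warn("koc_from_kow: log_kow outside regression range [3, 9]",
                      stacklevel=2)
    out = 10.0 ** (log_kow - 0.21) * 1.0e-3
    return float(out) if out.ndim == 0 else out


def kdoc_from_kow(log_kow):
    """DOC partition coefficient, Kdoc = 0.08 Kow (L/kg), returned in m3 kg-1.

    Always below Koc for the same compound (0.08 < 10**-0.21).
    """
    log_kow = np.asarray(log_kow, dtype=float)
    if np.any((log_kow < 3.0) | (log_kow > 9.0)):
        warnings.warn("kdoc_from_kow: log_kow outside regression range [3, 9]",
                      stacklevel=2)
    out = 0.08 * 10.0 ** log_kow * 1.0e-3
    return float(out) if out.ndim == 0 else out


def rain_concentration(c_gas, c_part, h_prime, w_p=DEFAULT_SCAVENGING_RATIO):
    """Rainwater concentration from air concentrations (ng m-3 rain).

    ``c_rain = c_gas / H' + W_p * c_part``: equilibrium gas washout plus
    particle scavenging with ratio ``W_p``.  Used to extrapolate rain
    boundary concentrations from measured gaseous and particulate air
    concentrations when no rain samples exist.
    """
    c_gas = np.asarray(c_gas, dtype=float)
    c_part = np.asarray(c_part, dtype=float)
    h_prime = np.asarray(h_prime, dtype=float)
    if np.any(c_gas < 0) or np.any(c_part < 0):
        raise InvalidInputError("rain_concentration: concentrations must be >= 0")
    if np.any(np.asarray(w_p) <= 0):
        raise InvalidInputError("rain_concentration: W_p must be > 0")
    if np.any((h_prime == 0) & (c_gas > 0)):
        raise DegenerateInputError("rain_concentration: H' = 0 with non-zero gas phase")
    gas_term = np.divide(c_gas, h_prime,
                         out=np.zeros(np.broadcast(c_gas, h_prime).shape),
                         where=np.asarray(h_prime) != 0)
    out = gas_term + w_p * c_part
    return float(out) if out.ndim == 0 else out
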