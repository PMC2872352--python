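"""Air-water interface fluxes: two-film diffusive exchange and deposition.

Sign convention follows the budget table: positive fluxes are inputs to the
water column.  Gross volatilization (always <= 0) and gross gaseous
absorption (always >= 0) are kept separate so the annual budget can report
them as individual lines.

Two-film closures (config-overridable through :class:`ProcessParams`):

* water film  k_w = 0.45 u10^1.64 cm h-1, scaled by (Sc_w/600)^-0.5
* air film    k_a = (0.2 u10 + 0.3) cm s-1, scaled by (18/M)^0.305
* overall     1/k_ol = 1/k_w + 1/(k_a H')
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidInputError

CM_PER_HOUR = 1.0 / 3.6e5  # m/s per cm/h
CM_PER_SECOND = 1.0e-2

DEFAULT_DEPOSITION_VELOCITY = 1.5e-3
"""Dry particle deposition velocity v_d, m s-1 (0.15 cm s-1)."""


@dataclass(frozen=True)
class AirForcing:
    """Atmospheric forcing over one box at one instant."""

    c_gas: float  # ng m-3
    c_part_air: float  # ng m-3
    rain_rate: float  # m s-1
    u10: float  # m s-1
    T_air: float  # K
    c_rain: float | None = None  # ng m-3; derived from air if None

    def __post_init__(self) -> None:
        if min(self.c_gas, self.c_part_air, self.rain_rate) < 0:
            raise InvalidInputError("AirForcing: concentrations and rain_rate must be >= 0")
        if self.c_rain is not None and self.c_rain < 0:
            raise InvalidInputError("AirForcing: c_rain must be >= 0")


@dataclass(frozen=True)
class AirWaterFluxes:
    """Interface fluxes in ng m-2 s-1, positive into the water column."""

    volatilization: float  # <= 0
    absorption: float  # >= 0
    dry_dep: float  # >= 0
    wet_dep: float  # >= 0

    def __post_init__(self) -> None:
        if self.volatilization > 0:
            raise InvalidInputError("volatilization must be <= 0")
        if min(self.absorption, self.dry_dep, self.wet_dep) < 0:
            raise InvalidInputError("absorption/deposition fluxes must be >= 0")

    @property
    def net(self) -> float:
        return self.volatilization + self.absorption + self.dry_dep + self.wet_dep


def water_kinematic_viscosity(T_water):
    """Kinematic viscosity of water, m2 s-1 (freshwater correlation)."""
    t = np.asarray(T_water, dtype=float) - 273.15
    return 1.79e-6 / (1.0 + 0.0337 * t + 0.000221 * t * t)


def aqueous_diffusivity(molar_mass):
    """Aqueous molecular diffusivity, m2 s-1, inverse-sqrt molar-mass scaling."""
    return 8.6e-9 / np.sqrt(np.asarray(molar_mass, dtype=float))


def schmidt_number_water(molar_mass, T_water):
    return water_kinematic_viscosity(T_water) / aqueous_diffusivity(molar_mass)


def water_film_velocity(u10, molar_mass, T_water):
    """Water-side transfer velocity, m s-1; zero at zero wind."""
    u10 = np.asarray(u10, dtype=float)
    if np.any(u10 < 0):
        raise InvalidInputError("water_film_velocity: u10 must be >= 0")
    sc = schmidt_number_water(molar_mass, T_water)
    return 0.45 * u10 ** 1.64 * CM_PER_HOUR * (sc / 600.0) ** -0.5


def air_film_velocity(u10, molar_mass):
    """Air-side transfer velocity, m s-1, diffusivity-scaled from water vapour."""
    u10 = np.asarray(u10, dtype=float)
    if np.any(u10 < 0):
        raise InvalidInputError("air_film_velocity: u10 must be >= 0")
    scale = (18.0 / np.asarray(molar_mass, dtype=float)) ** 0.305
    return (0.2 * u10 + 0.3) * CM_PER_SECOND * scale


def overall_from_films(k_w, k_a, h_prime):
    """Series-resistance combination 1/k_ol = 1/k_w + 1/(k_a H')."""
    k_w = np.asarray(k_w, dtype=float)
    k_a = np.asarray(k_a, dtype=float)
    h_prime = np.asarray(h_prime, dtype=float)
    if np.any(h_prime <= 0):
        raise DegenerateInputError("overall_from_films: H' must be > 0")
    gas_side = k_a * h_prime
    with np.errstate(divide="ignore"):
        r = 1.0 / k_w + 1.0 / gas_side
    out = np.where((k_w > 0) & (gas_side > 0), 1.0 / np.where(r > 0, r, np.inf), 0.0)
    return float(out) if out.ndim == 0 else out


def overall_transfer_velocity(u10, h_prime, T_water, molar_mass):
    """Overall air-water transfer velocity k_ol, m s-1.

    Never exceeds either single-film velocity; zero at zero wind (the
    chosen water-film closure has k_w(0) = 0).
    """
    k_w = water_film_velocity(u10, molar_mass, T_water)
    k_a = air_film_velocity(u10, molar_mass)
    return overall_from_films(k_w, k_a, h_prime)


def gross_diffusive_fluxes(k_ol, c_diss, c_gas, h_prime):
    """Gross volatilization (<= 0) and gaseous absorption (>= 0), ng m-2 s-1.

    Only the freely dissolved phase exchanges with the atmosphere; the net
    diffusive flux vanishes at air-water equilibrium c_diss = c_gas / H'.
    """
    k_ol = np.asarray(k_ol, dtype=float)
    c_diss = np.asarray(c_diss, dtype=float)
    c_gas = np.asarray(c_gas, dtype=float)
    h_prime = np.asarray(h_prime, dtype=float)
    if np.any(k_ol < 0) or np.any(c_diss < 0) or np.any(c_gas < 0):
        raise InvalidInputError("gross_diffusive_fluxes: inputs must be >= 0")
    if np.any(h_prime <= 0):
        raise DegenerateInputError("gross_diffusive_fluxes: H' must be > 0")
    volat = -k_ol * c_diss
    absorb = k_ol * c_gas / h_prime
    if volat.ndim == 0:
        return float(volat), float(absorb)
    return volat, absorb


def dry_deposition_flux(v_d, c_part_air):
    """Dry particle deposition flux v_d * c_part_air, ng m-2 s-1 (>= 0)."""
    v_d = np.asarray(v_d, dtype=float)
    c_part_air = np.asarray(c_part_air, dtype=float)
    if np.any(v_d < 0) or np.any(c_part_air < 0):
        raise InvalidInputError("dry_deposition_flux: inputs must be >= 0")
    out = v_d * c_part_air
    return float(out) if out.ndim == 0 else out


def wet_deposition_flux(rain_rate, c_rain):
    """Wet deposition flux rain_rate * c_rain, ng m-2 s-1 (>= 0)."""
    rain_rate = np.asarray(rain_rate, dtype=float)
    c_rain = np.asarray(c_rain, dtype=float)
    if np.any(rain_rate < 0) or np.any(c_rain < 0):
        raise InvalidInputError("wet_deposition_flux: inputs must be >= 0")
    out = rain_rate * c_rain
    return float(out) if out.ndim == 0 else out


def air_water_fluxes(forcing: AirForcing, c_diss: float, h_prime: float,
                     molar_mass: float, T_water: float,
                     v_d: float = DEFAULT_DEPOSITION_VELOCITY,
                     w_p: float = 2.0e5) -> AirWaterFluxes:
    """All four air-water interface fluxes for one box/congener/instant."""
    from .congeners import rain_concentration

    k_ol = overall_transfer_velocity(forcing.u10, h_prime, T_water, molar_mass)
    volat, absorb = gross_diffusive_fluxes(k_ol, c_diss, forcing.c_gas, h_prime)
    c_rain = forcing.c_rain
    if c_rain is None:
        c_rain = rain_concentration(forcing.c_gas, forcing.c_part_air, h_prime, w_p)
    return AirWaterFluxes(
        volatilization=volat,
        absorption=absorb,
        dry_dep=dry_deposition_flux(v_d, forcing.c_part_air),
        wet_dep=wet_deposition_flux(forcing.rain_rate, c_rain),
    )
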