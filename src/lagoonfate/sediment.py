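"""Sediment-water exchange and the two-layer surface sediment state.

The bed is represented by a surface mixed layer with a prognostic
contaminant concentration (ng per kg dry solids) over a deep layer held at
a fixed boundary concentration.  Processes at the sediment-water interface:
particle settling (water loss), resuspension (water gain) and porewater
diffusion (signed).  Between the two sediment layers: a lumped
physical-plus-biological exchange velocity and a burial flux; first-order
degradation acts on the surface-layer inventory.

Sign convention: fluxes in ng m-2 s-1, positive into the water column.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateInputError, InvalidInputError, StabilityError


@dataclass(frozen=True)
class SedimentState:
    """Two-layer sediment column state (per unit bed area)."""

    c_surf: float  # ng per kg dry solids, surface mixed layer
    c_deep: float  # ng per kg dry solids, fixed deep boundary
    h_surf: float = 0.05  # m
    porosity: float = 0.8
    rho_solid: float = 2600.0  # kg m-3
    f_oc_sed: float = 0.03  # kg OC per kg dry solids

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise InvalidInputError("SedimentState: porosity must be in (0, 1)")
        if self.h_surf <= 0:
            raise InvalidInputError("SedimentState: h_surf must be > 0")
        if self.c_surf < 0 or self.c_deep < 0:
            raise InvalidInputError("SedimentState: concentrations must be >= 0")

    @property
    def bulk_dry_density(self) -> float:
        """Dry solids per unit bulk sediment volume, kg m-3."""
        return (1.0 - self.porosity) * self.rho_solid

    @property
    def areal_solids(self) -> float:
        """Dry solids per unit bed area in the surface layer, kg m-2."""
        return self.h_surf * self.bulk_dry_density

    @property
    def inventory(self) -> float:
        """Surface-layer contaminant inventory, ng m-2."""
        return self.c_surf * self.areal_solids


@dataclass(frozen=True)
class SedimentWaterFluxes:
    """Per-process sediment fluxes, ng m-2 s-1, positive into the water column.

    ``burial``, ``sed_degradation`` and ``settling`` are water/inventory
    losses (<= 0); ``resuspension`` is a gain (>= 0); ``diffusion`` and
    ``deep_exchange`` are signed.
    """

    settling: float
    resuspension: float
    diffusion: float
    burial: float
    sed_degradation: float
    deep_exchange: float = 0.0

    def __post_init__(self) -> None:
        if self.settling > 0 or self.burial > 0 or self.sed_degradation > 0:
            raise InvalidInputError("settling/burial/degradation fluxes must be <= 0")
        if self.resuspension < 0:
            raise InvalidInputError("resuspension flux must be >= 0")


def settling_flux(w_s, c_part):
    """Particle settling loss -w_s * c_part, ng m-2 s-1 (<= 0)."""
    w_s = np.asarray(w_s, dtype=float)
    c_part = np.asarray(c_part, dtype=float)
    if np.any(w_s < 0) or np.any(c_part < 0):
        raise InvalidInputError("settling_flux: inputs must be >= 0")
    out = -w_s * c_part
    return float(out) if out.ndim == 0 else out


def resuspension_flux(r_s, c_surf):
    """Resuspension gain r_s * c_surf, ng m-2 s-1 (>= 0).

    ``r_s`` is a solids resuspension rate in kg m-2 s-1; the flux is
    independent of the water-column concentration.
    """
    r_s = np.asarray(r_s, dtype=float)
    c_surf = np.asarray(c_surf, dtype=float)
    if np.any(r_s < 0) or np.any(c_surf < 0):
        raise InvalidInputError("resuspension_flux: inputs must be >= 0")
    out = r_s * c_surf
    return float(out) if out.ndim == 0 else out


def porewater_concentration(c_surf, koc, f_oc_sed):
    """Equilibrium porewater concentration c_surf / (Koc * f_oc), ng m-3."""
    c_surf = np.asarray(c_surf, dtype=float)
    kd = np.asarray(koc, dtype=float) * np.asarray(f_oc_sed, dtype=float)
    if np.any(kd <= 0):
        raise DegenerateInputError("porewater_concentration: Koc * f_oc must be > 0")
    if np.any(c_surf < 0):
        raise InvalidInputError("porewater_concentration: c_surf must be >= 0")
    out = c_surf / kd
    return float(out) if out.ndim == 0 else out


def sediment_water_diffusion(k_sw, c_pore, c_diss):
    """Diffusive porewater exchange k_sw * (c_pore - c_diss), positive toward water."""
    k_sw = np.asarray(k_sw, dtype=float)
    if np.any(k_sw < 0):
        raise InvalidInputError("sediment_water_diffusion: k_sw must be >= 0")
    out = k_sw * (np.asarray(c_pore, dtype=float) - np.asarray(c_diss, dtype=float))
    return float(out) if out.ndim == 0 else out


def sediment_inventory_tendency(c_surf, c_deep, settling, resuspension, diffusion,
                                areal_solids, bulk_dry_density,
                                gamma_sed, w_burial, deg_rate_sediment):
    """Array core of the surface-layer mass balance.

    Returns ``(dI_dt, burial_flux, deg_flux, deep_flux)`` where ``dI_dt`` is
    the surface-layer inventory tendency in ng m-2 s-1 and the three fluxes
    follow the positive-into-water sign convention (burial and degradation
    <= 0; deep exchange signed, positive = gain from the deep layer).
    """
    c_surf = np.asarray(c_surf, dtype=float)
    deep_flux = gamma_sed * bulk_dry_density * (np.asarray(c_deep, dtype=float) - c_surf)
    burial_flux = -w_burial * bulk_dry_density * c_surf
    deg_flux = -deg_rate_sediment * c_surf * areal_solids
    dI_dt = (-np.asarray(settling, dtype=float)
             - np.asarray(resuspension, dtype=float)
             - np.asarray(diffusion, dtype=float)
             + deep_flux + burial_flux + deg_flux)
    return dI_dt, burial_flux, deg_flux, deep_flux


def sediment_layer_step(state: SedimentState, settling: float, resuspension: float,
                        diffusion: float, dt: float,
                        gamma_sed: float = 2.0e-10,
                        w_burial: float = 3.17e-11,
                        deg_rate_sediment: float = 0.0,
                        ) -> tuple[SedimentState, SedimentWaterFluxes]:
    """Advance the surface sediment layer one explicit-Euler step.

    ``settling`` (<= 0, relative to the water column), ``resuspension``
    (>= 0) and ``diffusion`` (signed) are the interface fluxes already
    computed for this step; the layer additionally exchanges with the deep
    boundary, buries and degrades.  Raises :class:`StabilityError` when the
    first-order loss rates would empty the layer within one step.
    """
    if dt <= 0:
        raise InvalidInputError("sediment_layer_step: dt must be > 0")
    areal = state.areal_solids
    loss_rate = ((gamma_sed + w_burial) * state.bulk_dry_density / areal
                 + deg_rate_sediment)
    if dt * loss_rate >= 1.0:
        raise StabilityError(
            f"sediment_layer_step: dt={dt} exceeds stability bound "
            f"{1.0 / loss_rate:.3g} s for the surface layer")
    dI_dt, burial, deg, deep = sediment_inventory_tendency(
        state.c_surf, state.c_deep, settling, resuspension, diffusion,
        areal, state.bulk_dry_density, gamma_sed, w_burial, deg_rate_sediment)
    new_c = state.c_surf + dt * float(dI_dt) / areal
    if new_c < 0:
        raise StabilityError("sediment_layer_step: surface concentration went negative")
    fluxes = SedimentWaterFluxes(settling=settling, resuspension=resuspension,
                                 diffusion=diffusion, burial=float(burial),
                                 sed_degradation=float(deg), deep_exchange=float(deep))
    return replace(state, c_surf=new_c), fluxes
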