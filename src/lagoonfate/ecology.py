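"""Minimal plankton ecosystem model supplying POC and DOC to partitioning.

Eight pools: two phytoplankton (P1 small/fast, P2 large/slow), two
zooplankton (Z1 micro, grazing P1 and bacteria; Z2 meso, grazing P2 and
Z1), bacteria B, detritus D and dissolved organic carbon DOC, all in
mg C m-3, plus one dissolved inorganic nutrient N in mmol m-3.

Closures: Monod nutrient limitation, saturating light response, Q10
temperature factor, Holling-II grazing with fixed assimilation efficiency,
linear (temperature-dependent) mortality to detritus, first-order detritus
dissolution to DOC, and bacterial DOC uptake with a fixed growth
efficiency.  Carbon accounting is closed: the sum of all carbon-pool
tendencies equals gross primary production minus total respiration, which
is the single external loss.  Nutrient is consumed by photosynthesis and
returned by respiration with a fixed C:N quota.

The parameter defaults produce a plausible Mediterranean-lagoon seasonal
cycle (spring bloom, POC of order 1e2-1e3 mg C m-3); they are generic and
make no claim beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

PER_DAY = 1.0 / 86400.0

POOLS = ("P1", "P2", "Z1", "Z2", "B", "D", "DOC_e", "N")
N_POOLS = len(POOLS)

CARBON_PER_NITROGEN = 6.625 * 12.0  # mg C per mmol N (Redfield)


@dataclass(frozen=True)
class EcologyState:
    """Plankton ecosystem state; carbon pools mg C m-3, nutrient mmol m-3."""

    P1: float
    P2: float
    Z1: float
    Z2: float
    B: float
    D: float
    DOC_e: float
    N: float

    def __post_init__(self) -> None:
        if min(self.as_array()) < 0:
            raise InvalidInputError("EcologyState: all pools must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.P1, self.P2, self.Z1, self.Z2,
                         self.B, self.D, self.DOC_e, self.N], dtype=float)

    @classmethod
    def from_array(cls, a) -> "EcologyState":
        return cls(*(float(x) for x in np.asarray(a, dtype=float)))


@dataclass(frozen=True)
class EcologyParams:
    """Rate constants (per day unless noted) and half-saturation constants."""

    mu_max: tuple[float, float] = (2.0, 1.5)  # phytoplankton max growth, d-1
    k_n: tuple[float, float] = (1.0, 2.0)  # nutrient half-saturation, mmol m-3
    k_i: tuple[float, float] = (40.0, 60.0)  # light half-saturation, W m-2
    exudation_frac: float = 0.10  # fraction of GPP exuded to DOC
    g_max: tuple[float, float] = (1.0, 0.8)  # Z1, Z2 max grazing, d-1
    k_g: float = 50.0  # grazing half-saturation, mg C m-3
    assimilation: float = 0.7  # assimilated fraction of grazing
    zoo_respiration: float = 0.3  # respired fraction of assimilation
    u_max_bact: float = 1.0  # bacterial max DOC uptake, d-1
    k_doc: float = 500.0  # mg C m-3
    bact_growth_eff: float = 0.3
    mort: float = 0.05  # linear mortality (P, Z, B), d-1
    dissolution: float = 0.05  # detritus -> DOC, d-1
    q10: float = 2.0
    t_ref: float = 293.15  # K


@dataclass(frozen=True)
class CarbonDiagnostics:
    """Closure terms of one derivative evaluation, mg C m-3 s-1."""

    gpp: float | np.ndarray
    respiration: float | np.ndarray


DEFAULT_BOUNDARY = EcologyState(P1=1.0, P2=1.0, Z1=0.5, Z2=0.5,
                                B=5.0, D=20.0, DOC_e=800.0, N=8.0)


def _derivative_arrays(pools, T_water, irradiance, dilution, params, boundary):
    """Vectorized tendency computation on a (..., 8) pool array."""
    p = params
    P1, P2, Z1, Z2, B, D, DOC, N = (pools[..., i] for i in range(N_POOLS))
    f_t = p.q10 ** ((np.asarray(T_water, dtype=float) - p.t_ref) / 10.0)
    irr = np.asarray(irradiance, dtype=float)

    gpp = np.empty_like(pools[..., 0:2])
    for i, (mu, kn, ki) in enumerate(zip(p.mu_max, p.k_n, p.k_i)):
        f_i = irr / (irr + ki)
        f_n = N / (kn + N)
        gpp[..., i] = mu * PER_DAY * f_t * f_i * f_n * (P1 if i == 0 else P2)
    gpp_total = gpp[..., 0] + gpp[..., 1]
    exud = p.exudation_frac * gpp_total

    # Holling-II grazing on combined prey, apportioned by availability
    prey1 = P1 + B
    prey2 = P2 + Z1
    graz1 = p.g_max[0] * PER_DAY * f_t * prey1 / (p.k_g + prey1) * Z1
    graz2 = p.g_max[1] * PER_DAY * f_t * prey2 / (p.k_g + prey2) * Z2
    w1 = np.where(prey1 > 0, np.divide(P1, prey1, out=np.zeros_like(prey1),
                                       where=prey1 > 0), 0.0)
    w2 = np.where(prey2 > 0, np.divide(P2, prey2, out=np.zeros_like(prey2),
                                       where=prey2 > 0), 0.0)
    graz_p1, graz_b = graz1 * w1, graz1 * (1.0 - w1)
    graz_p2, graz_z1 = graz2 * w2, graz2 * (1.0 - w2)
    assim1, assim2 = p.assimilation * graz1, p.assimilation * graz2
    egest = (1.0 - p.assimilation) * (graz1 + graz2)
    z_resp = p.zoo_respiration * (assim1 + assim2)

    upt = p.u_max_bact * PER_DAY * f_t * DOC / (p.k_doc + DOC) * B
    b_resp = (1.0 - p.bact_growth_eff) * upt

    m = p.mort * PER_DAY * f_t
    diss = p.dissolution * PER_DAY * f_t * D

    tend = np.empty_like(pools)
    tend[..., 0] = gpp[..., 0] * (1.0 - p.exudation_frac) - graz_p1 - m * P1
    tend[..., 1] = gpp[..., 1] * (1.0 - p.exudation_frac) - graz_p2 - m * P2
    tend[..., 2] = assim1 * (1.0 - p.zoo_respiration) - graz_z1 - m * Z1
    tend[..., 3] = assim2 * (1.0 - p.zoo_respiration) - m * Z2
    tend[..., 4] = p.bact_growth_eff * upt - graz_b - m * B
    tend[..., 5] = egest + m * (P1 + P2 + Z1 + Z2 + B) - diss
    tend[..., 6] = exud + diss - upt
    tend[..., 7] = (-gpp_total + z_resp + b_resp) / CARBON_PER_NITROGEN

    if dilution is not None and np.any(np.asarray(dilution) != 0):
        bnd = boundary.as_array() if isinstance(boundary, EcologyState) else np.asarray(boundary)
        tend = tend + np.asarray(dilution)[..., None] * (bnd - pools)

    return tend, gpp_total, z_resp + b_resp


def ecosystem_derivatives(state, T_water, irradiance, dilution=0.0,
                          params: EcologyParams | None = None,
                          boundary: EcologyState = DEFAULT_BOUNDARY):
    """Tendencies d(state)/dt plus carbon-closure diagnostics.

    Accepts an :class:`EcologyState` or a (..., 8) array in :data:`POOLS`
    order.  ``dilution`` (s-1) relaxes every pool toward ``boundary``,
    representing exchange with adjacent waters; it is external to the
    carbon closure.  Returns ``(tendencies, CarbonDiagnostics)``.
    """
    if params is None:
        params = EcologyParams()
    as_state = isinstance(state, EcologyState)
    pools = state.as_array() if as_state else np.asarray(state, dtype=float)
    if pools.shape[-1] != N_POOLS:
        raise InvalidInputError(f"ecology state must have {N_POOLS} pools")
    if np.any(pools < 0):
        raise InvalidInputError("ecosystem_derivatives: negative pool value")
    tend, gpp, resp = _derivative_arrays(pools, T_water, irradiance,
                                         dilution, params, boundary)
    diag = CarbonDiagnostics(gpp=float(gpp) if np.ndim(gpp) == 0 else gpp,
                             respiration=float(resp) if np.ndim(resp) == 0 else resp)
    if as_state:
        return tend, diag
    return tend, diag


def organic_carbon_pools(state):
    """(POC, DOC) in kg C m-3 from an ecology state.

    POC is the sum of both phytoplankton, both zooplankton, bacteria and
    detritus; the 1e-6 factor converts mg C m-3 to kg C m-3.
    """
    pools = state.as_array() if isinstance(state, EcologyState) else np.asarray(state, dtype=float)
    poc = pools[..., 0:6].sum(axis=-1) * 1.0e-6
    doc = pools[..., 6] * 1.0e-6
    if np.ndim(poc) == 0:
        return float(poc), float(doc)
    return poc, doc
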