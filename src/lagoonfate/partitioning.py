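"""Equilibrium three-phase partitioning of the water-column contaminant.

Total concentration splits into freely dissolved, DOC-bound and particulate
fractions assuming local (instantaneous) sorption equilibrium with the
organic-carbon pools supplied by the ecosystem module:

    f_diss = 1 / (1 + Koc*POC + Kdoc*DOC)
    f_part = Koc*POC * f_diss
    f_doc  = Kdoc*DOC * f_diss

with Koc/Kdoc in m3 per kg organic carbon and POC/DOC in kg C m-3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class EnvironmentState:
    """Local water-column environment seen by the partitioning step.

    POC and DOC are organic-carbon sorbent concentrations in kg C m-3
    (converted from the ecology module's mg C m-3 with a 1e-6 factor).
    """

    T_water: float  # K
    salinity: float  # PSS78
    POC: float  # kg C m-3
    DOC: float  # kg C m-3
    depth: float  # m

    def __post_init__(self) -> None:
        if self.POC < 0 or self.DOC < 0:
            raise InvalidInputError("EnvironmentState: POC and DOC must be >= 0")
        if self.depth <= 0:
            raise InvalidInputError("EnvironmentState: depth must be > 0")


@dataclass(frozen=True)
class PhaseDistribution:
    """Dimensionless phase fractions; must sum to 1."""

    f_diss: float
    f_doc: float
    f_part: float

    def __post_init__(self) -> None:
        for f in (self.f_diss, self.f_doc, self.f_part):
            if not 0.0 <= f <= 1.0:
                raise InvalidInputError("phase fractions must lie in [0, 1]")
        if abs(self.f_diss + self.f_doc + self.f_part - 1.0) > 1e-12:
            raise InvalidInputError("phase fractions must sum to 1")


@dataclass(frozen=True)
class PhaseConcentrations:
    """Phase-resolved concentrations, ng m-3 water; components sum to total."""

    c_total: float
    c_diss: float
    c_doc: float
    c_part: float

    def __post_init__(self) -> None:
        for c in (self.c_total, self.c_diss, self.c_doc, self.c_part):
            if c < 0:
                raise InvalidInputError("phase concentrations must be >= 0")
        ref = max(self.c_total, 1e-300)
        if abs(self.c_diss + self.c_doc + self.c_part - self.c_total) > 1e-9 * ref:
            raise InvalidInputError("phase concentrations must sum to c_total")


def phase_fraction_arrays(koc, kdoc, poc, doc):
    """Vectorized fraction computation; returns (f_diss, f_doc, f_part) arrays."""
    koc = np.asarray(koc, dtype=float)
    kdoc = np.asarray(kdoc, dtype=float)
    poc = np.asarray(poc, dtype=float)
    doc = np.asarray(doc, dtype=float)
    if np.any(koc < 0) or np.any(kdoc < 0):
        raise InvalidInputError("three_phase_fractions: koc and kdoc must be >= 0")
    if np.any(poc < 0) or np.any(doc < 0):
        raise InvalidInputError("three_phase_fractions: POC and DOC must be >= 0")
    r_part = koc * poc
    r_doc = kdoc * doc
    f_diss = 1.0 / (1.0 + r_part + r_doc)
    return f_diss, r_doc * f_diss, r_part * f_diss


def three_phase_fractions(koc: float, kdoc: float, env: EnvironmentState) -> PhaseDistribution:
    """Split unit total concentration across dissolved, DOC and particle phases."""
    f_diss, f_doc, f_part = phase_fraction_arrays(koc, kdoc, env.POC, env.DOC)
    # renormalize away the last-ulp drift so the type invariant holds exactly
    s = f_diss + f_doc + f_part
    return PhaseDistribution(float(f_diss / s), float(f_doc / s), float(f_part / s))


def phase_concentrations(c_total: float, dist: PhaseDistribution) -> PhaseConcentrations:
    """Apply a phase distribution to a total concentration."""
    if c_total < 0:
        raise InvalidInputError("phase_concentrations: c_total must be >= 0")
    c_diss = dist.f_diss * c_total
    c_doc = dist.f_doc * c_total
    c_part = dist.f_part * c_total
    return PhaseConcentrations(c_diss + c_doc + c_part, c_diss, c_doc, c_part)
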