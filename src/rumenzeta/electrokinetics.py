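"""Electrophoretic mobility <-> zeta potential conversion (Henry equation).

For a particle in a medium of dynamic viscosity eta, relative permittivity
eps_r and vacuum permittivity eps0, the Henry relation is

    mu_e = (2/3) * eps_r * eps0 * zeta * f(ka) / eta

so  zeta = 3 * mu_e * eta / (2 * eps_r * eps0 * f(ka)).

f(ka) is the Henry factor: 1 in the Hueckel limit (small ka), 3/2 in the
Smoluchowski limit (large ka, the usual regime for bacterial cells in aqueous
media and the convention of ZetaPALS-class instruments).  The default medium
is water at 39 C (the incubation temperature): eta = 6.66e-4 Pa.s,
eps_r = 73.0.  With f = 3/2 these constants give ~10.3 mV of zeta per
1e-8 m^2 V^-1 s^-1 of mobility, matching the ~10.2 ratio seen in the published
paired measurements; f = 1 selects the bare-3/2-numerator form.

Mobility is expressed in 1e-8 m^2 V^-1 s^-1 (= um.cm/V/s) throughout, zeta in
mV.  The instrument's exact settings are not published; the defaults here are
literature values for the medium, not asserted instrument constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, RumenZetaError
from .io import TimeScale1Record

__all__ = [
    "MediumProperties",
    "zeta_from_mobility",
    "mobility_from_zeta",
    "estimate_conversion_constant",
    "ConversionEstimate",
]

MOBILITY_UNIT = 1e-8  # m^2 V^-1 s^-1 per mobility unit


@dataclass(frozen=True)
class MediumProperties:
    """Dispersion-medium constants entering the Henry conversion."""

    viscosity: float = 6.66e-4          # Pa.s, water at 39 C
    dielectric_constant: float = 73.0   # unitless, water at 39 C
    vacuum_permittivity: float = 8.854e-12  # F/m
    henry_factor: float = 1.5           # 1 = Hueckel, 1.5 = Smoluchowski

    def __post_init__(self):
        if not (self.viscosity > 0 and self.dielectric_constant > 0):
            raise ValueError("viscosity and dielectric constant must be positive")
        if not 1.0 <= self.henry_factor <= 1.5:
            raise ValueError("henry_factor must lie in [1, 1.5]")

    @property
    def mv_per_mobility_unit(self) -> float:
        """Conversion slope: zeta [mV] per mobility [1e-8 m^2/V/s]."""
        eps = self.dielectric_constant * self.vacuum_permittivity
        return 3.0 * MOBILITY_UNIT * self.viscosity / (2.0 * eps * self.henry_factor) * 1e3


def zeta_from_mobility(mobility, medium: MediumProperties = MediumProperties()):
    """Zeta potential (mV) from electrophoretic mobility (1e-8 m^2/V/s).

    Accepts scalars or arrays; linear and sign-preserving.
    """
    mob = np.asarray(mobility, dtype=float)
    if not np.all(np.isfinite(mob)):
        raise RumenZetaError("mobility must be finite")
    out = mob * medium.mv_per_mobility_unit
    return float(out) if np.isscalar(mobility) else out


def mobility_from_zeta(zeta, medium: MediumProperties = MediumProperties()):
    """Inverse of :func:`zeta_from_mobility`."""
    z = np.asarray(zeta, dtype=float)
    if not np.all(np.isfinite(z)):
        raise RumenZetaError("zeta must be finite")
    out = z / medium.mv_per_mobility_unit
    return float(out) if np.isscalar(zeta) else out


@dataclass(frozen=True)
class ConversionEstimate:
    """Empirical zeta/mobility slope with per-record relative residuals."""

    constant: float                     # mV per mobility unit
    residuals: tuple[float, ...]        # (ratio_i - constant) / constant


def estimate_conversion_constant(
    records: Sequence[TimeScale1Record],
) -> ConversionEstimate:
    """Median zeta/mobility ratio over paired measurements.

    Robust check that a table of paired (mobility, zeta) columns follows a
    single Henry-type conversion; residuals flag rows that deviate.
    """
    pairs = [(r.mobility, r.zeta) for r in records if r.mobility != 0.0]
    if not pairs:
        raise DegenerateInputError(
            "need at least one record with nonzero mobility"
        )
    ratios = np.array([z / m for m, z in pairs])
    k = float(np.median(ratios))
    if k == 0.0 or not math.isfinite(k):
        raise DegenerateInputError("degenerate zeta/mobility ratios")
    residuals = tuple(float(v) for v in (ratios - k) / k)
    return ConversionEstimate(constant=k, residuals=residuals)
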