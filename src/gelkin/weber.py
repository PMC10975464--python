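"""Dimensionless sol-gel equilibrium analysis.

A dispersed cluster of radius R rotating in a Couette shear field is stable
while surface tension dominates the shear stress.  The balance is measured by
the Weber number

    We = R * eta * nu / (2 * gamma),

the ratio of shear stress (Newton: tau = eta*nu) to the Laplace pressure
2*gamma/R.  At hydrostatic equilibrium We = 1; generalized against the kinetic
ratio Wi = k_minus/k_plus = A0/B_inf, the single dimensionless criterion
We - Wi = 0 separates growth-dominated from breakup-dominated regimes.

Viscosities enter in mPa·s (instrument convention) and are converted to Pa·s
internally; all other quantities SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import DomainError

__all__ = [
    "Regime",
    "WeberState",
    "weber_number",
    "critical_radius",
    "wi_number",
    "wi_from_composition",
    "classify_regime",
    "angular_velocity",
    "centrifugal_force",
    "shear_rate_from_rpm",
]

_MPAS_TO_PAS = 1e-3

#: Default half-width of the equilibrium band |We - Wi| <= eps.  The analytic
#: balance is exact; numerics need a band.  Widen it for fitted inputs.
DEFAULT_EPS = 1e-9


class Regime(str, Enum):
    """Which of creation (surface tension) and destruction (shear) prevails."""

    GROWTH_DOMINATED = "growth_dominated"
    EQUILIBRIUM = "equilibrium"
    BREAKUP_DOMINATED = "breakup_dominated"


def weber_number(R: float, eta: float, nu: float, gamma: float) -> float:
    """Weber number We = R * eta * nu / (2 * gamma), dimensionless.

    Parameters: R in m; eta in mPa·s; nu (shear rate) in 1/s; gamma in N/m.
    Linear in each of R, eta, nu and inverse in gamma.
    """
    if R <= 0:
        raise DomainError("R must be strictly positive")
    if gamma <= 0:
        raise DomainError("gamma must be strictly positive")
    if eta < 0 or nu < 0:
        raise DomainError("eta and nu must be non-negative")
    return R * (eta * _MPAS_TO_PAS) * nu / (2.0 * gamma)


def critical_radius(eta: float, nu: float, gamma: float) -> float:
    """Radius R* = 2*gamma/(eta*nu) at which We = 1 (hydrostatic balance).

    Returns ``math.inf`` at nu = 0: no flow, no breakup at any size.
    eta in mPa·s, gamma in N/m.
    """
    if eta <= 0 or gamma <= 0:
        raise DomainError("eta and gamma must be strictly positive")
    if nu < 0:
        raise DomainError("nu must be non-negative")
    if nu == 0:
        return math.inf
    return 2.0 * gamma / ((eta * _MPAS_TO_PAS) * nu)


def wi_number(k_minus: float, k_plus: float) -> float:
    """Kinetic ratio Wi = k_minus / k_plus = 1/K, dimensionless.

    Equals A0/B_inf whenever B_inf = k_plus*A0/k_minus (see
    :func:`wi_from_composition`).  Wi = 0 is irreversible aggregation.
    """
    if k_plus <= 0:
        raise DomainError("k_plus must be strictly positive")
    if k_minus < 0:
        raise DomainError("k_minus must be non-negative")
    return k_minus / k_plus


def wi_from_composition(A0: float, B_inf: float) -> float:
    """Wi expressed through composition, Wi = A0 / B_inf."""
    if B_inf <= 0:
        raise DomainError("B_inf must be strictly positive")
    if A0 < 0:
        raise DomainError("A0 must be non-negative")
    return A0 / B_inf


def classify_regime(We: float, Wi: float = 1.0, eps: float = DEFAULT_EPS) -> Regime:
    """Classify the sign of We - Wi within a tolerance band eps.

    |We - Wi| <= eps: equilibrium (creation and destruction balance).
    We - Wi < -eps: growth-dominated (low shear or small particles).
    We - Wi > +eps: breakup-dominated (high shear or large particles).
    """
    if We < 0 or Wi < 0:
        raise DomainError("We and Wi must be non-negative")
    if eps <= 0:
        raise DomainError("eps must be strictly positive")
    diff = We - Wi
    if abs(diff) <= eps:
        return Regime.EQUILIBRIUM
    return Regime.BREAKUP_DOMINATED if diff > 0 else Regime.GROWTH_DOMINATED


@dataclass(frozen=True)
class WeberState:
    """A (We, Wi) pair with its regime label."""

    We: float
    Wi: float
    regime: Regime

    @classmethod
    def evaluate(cls, We: float, Wi: float = 1.0, eps: float = DEFAULT_EPS):
        return cls(We=We, Wi=Wi, regime=classify_regime(We, Wi, eps))


def angular_velocity(nu: float) -> float:
    """Rotation rate of a no-slip sphere in simple shear, omega = nu/2, rad/s.

    Independent of particle radius (Einstein/Jeffery result).
    """
    if nu < 0:
        raise DomainError("nu must be non-negative")
    return nu / 2.0


def centrifugal_force(m_particle: float, omega: float, R: float) -> float:
    """Centrifugal (gyrostatic) force m * omega**2 * R at the surface, N.

    Grows with R at fixed omega: the instability argument for large clusters.
    """
    if m_particle < 0 or omega < 0 or R < 0:
        raise DomainError("arguments must be non-negative")
    return m_particle * omega**2 * R


def shear_rate_from_rpm(rpm: float, geometry_factor: float = 1.0) -> float:
    """Convert viscometer rotational speed to a nominal shear rate, 1/s.

    nu = geometry_factor * 2*pi*rpm/60.  The Couette geometry factor is
    instrument-specific (cylinder radii are not part of this model); with the
    default factor 1 this is the raw angular frequency, and only *ratios* of
    shear rates are meaningful across conditions.
    """
    if rpm < 0:
        raise DomainError("rpm must be non-negative")
    if geometry_factor <= 0:
        raise DomainError("geometry_factor must be strictly positive")
    return geometry_factor * 2.0 * math.pi * rpm / 60.0
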