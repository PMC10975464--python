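"""Macroscopic bounded-ripening-growth kinetics.

The dispersed-phase volume fraction ``B`` of a gelling dispersion obeys an
autocatalytic rate law with negative feedback,

    dB/dt = (k1 - k_minus * B) * B,

whose solution is the logistic sigmoid saturating at the equilibrium fraction
``B_inf = k1 / k_minus``.  The forward constant ``k1`` is controlled by the
surface tension of the dispersed clusters (it incorporates the free-monomer
concentration ``A0``), the reverse constant ``k_minus`` by the applied shear
rate.  Viscosity maps affinely onto the dispersed fraction through the dilute
Einstein relation ``eta = eta0 * (1 + kE * B)``.

This module is a pure computational kernel: closed forms only, no I/O, no
state.  All lengths are SI metres, times seconds, viscosities mPa·s
(instrument convention), surface tensions N/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, DomainError, NoEquilibriumError

__all__ = [
    "BOLTZMANN",
    "LogisticParams",
    "FluidProperties",
    "EinsteinMap",
    "logistic_rate",
    "logistic_solution",
    "first_order_solution",
    "viscosity_from_fraction",
    "fraction_from_viscosity",
    "laplace_pressure",
    "kelvin_concentration",
    "equilibrium_fraction",
    "inflection_time",
]

#: Boltzmann constant, J/K.  The Kelvin exponent is 2*gamma*mu/(kB*T*R) with
#: ``mu`` interpreted as a *molecular* volume in m^3 (dimensionally consistent
#: pairing; the molar-volume/R_gas pairing differs by Avogadro's number).
BOLTZMANN = 1.380649e-23

_CONSISTENCY_RTOL = 1e-9


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the logistic kinetics (k1, k_minus, B0, B_inf).

    Parameters
    ----------
    k1
        Forward rate constant, 1/s; incorporates the (constant) free-monomer
        concentration A0, i.e. k1 = k_plus * A0.
    k_minus
        Reverse rate coefficient, 1/s per unit volume fraction.
    B0
        Initial dispersed-phase volume fraction, in [0, 1).
    B_inf
        Equilibrium volume fraction, in (0, 1).  When ``k_minus > 0`` it must
        equal ``k1 / k_minus``; pass ``None`` to have it derived.
    """

    k1: float
    k_minus: float
    B0: float
    B_inf: float | None = None

    def __post_init__(self):
        if self.k1 < 0 or self.k_minus < 0:
            raise DomainError("rate constants must be non-negative")
        if not 0.0 <= self.B0 < 1.0:
            raise DomainError(f"B0={self.B0} outside [0, 1)")
        if self.B_inf is None:
            if self.k_minus == 0:
                raise NoEquilibriumError(
                    "k_minus = 0 has no equilibrium; supply B_inf explicitly"
                )
            object.__setattr__(self, "B_inf", self.k1 / self.k_minus)
        b_inf = self.B_inf
        if not 0.0 < b_inf < 1.0:
            raise DomainError(f"B_inf={b_inf} outside (0, 1)")
        if self.k_minus > 0:
            derived = self.k1 / self.k_minus
            if abs(b_inf - derived) > _CONSISTENCY_RTOL * max(b_inf, derived):
                raise DomainError(
                    f"B_inf={b_inf} inconsistent with k1/k_minus={derived}"
                )

    @classmethod
    def from_equilibrium(cls, k1: float, B_inf: float, B0: float) -> "LogisticParams":
        """Construct from (k1, B_inf, B0), deriving k_minus = k1 / B_inf."""
        if B_inf <= 0:
            raise DomainError("B_inf must be positive")
        return cls(k1=k1, k_minus=k1 / B_inf, B0=B0, B_inf=B_inf)

    @property
    def supersaturated(self) -> bool:
        """True when the initial fraction exceeds the equilibrium fraction."""
        return self.B0 > self.B_inf


@dataclass(frozen=True)
class FluidProperties:
    """Physical constants of the dispersion.

    eta0: continuous-phase viscosity, mPa·s.  gamma: cluster/medium interfacial
    tension, N/m.  D: effective monomer diffusion coefficient, m²/s.  mu:
    molecular volume of the aggregating unit, m³.  T: absolute temperature, K.
    delta_rho: density difference, kg/m³ (carried for completeness).
    R_dissolve: radius below which a cluster dissolves outright, m.
    """

    eta0: float
    gamma: float
    D: float
    mu: float
    T: float
    delta_rho: float = 0.0
    R_dissolve: float = 0.0

    def __post_init__(self):
        for name in ("eta0", "gamma", "D", "mu", "T"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if self.R_dissolve < 0:
            raise DomainError("R_dissolve must be non-negative")

    @property
    def kelvin_length(self) -> float:
        """Capillary length 2*gamma*mu/(kB*T) of the Kelvin exponent, m."""
        return 2.0 * self.gamma * self.mu / (BOLTZMANN * self.T)


@dataclass(frozen=True)
class EinsteinMap:
    """Affine dilute-dispersion viscosity map eta = eta0 * (1 + kE * B)."""

    eta0: float
    kE: float = 2.5

    def __post_init__(self):
        if self.eta0 <= 0 or self.kE <= 0:
            raise DomainError("eta0 and kE must be strictly positive")


def _check_fraction(B, name: str = "B") -> np.ndarray:
    arr = np.asarray(B, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise DomainError(f"{name} outside [0, 1]")
    return arr


def logistic_rate(B, p: LogisticParams):
    """Rate dB/dt = k1*B - k_minus*B**2 of the bounded kinetics, 1/s.

    Positive below the equilibrium fraction, negative above it, zero at the
    absorbing state B=0 and at the fixed point B=B_inf.
    """
    arr = _check_fraction(B)
    out = p.k1 * arr - p.k_minus * arr**2
    return out if out.ndim else float(out)


def logistic_solution(t, p: LogisticParams):
    """Closed-form sigmoid B(t) = B_inf / (1 + ((B_inf-B0)/B0) exp(-k1 t)).

    Monotone between B0 and B_inf: rising for an undersaturated start
    (B0 < B_inf), decaying for a supersaturated one.  Undefined at B0 = 0
    (the ODE's answer there is identically zero; callers must special-case),
    so that input raises :class:`DegenerateInputError`.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise DomainError("t must be non-negative")
    if p.B0 == 0:
        raise DegenerateInputError(
            "B0 = 0 makes the sigmoid undefined; the ODE solution is B(t) = 0"
        )
    ratio = (p.B_inf - p.B0) / p.B0
    out = p.B_inf / (1.0 + ratio * np.exp(-p.k1 * tt))
    return out if out.ndim else float(out)


def first_order_solution(t, B0: float, k1: float):
    """Unbounded early-ripening exponential B(t) = B0 * exp(k1 t).

    This is the zero-shear-feedback (k_minus = 0) limit, used during pause
    phases of the rheological history.  The formula is pure and unbounded;
    scenario code applies any physical ceiling.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise DomainError("t must be non-negative")
    out = B0 * np.exp(k1 * tt)
    return out if out.ndim else float(out)


def viscosity_from_fraction(B, m: EinsteinMap):
    """Einstein viscosity eta = eta0 * (1 + kE * B), mPa·s."""
    arr = _check_fraction(B)
    out = m.eta0 * (1.0 + m.kE * arr)
    return out if out.ndim else float(out)


def fraction_from_viscosity(eta, m: EinsteinMap):
    """Invert the Einstein map: B = (eta/eta0 - 1)/kE.

    Sub-baseline viscosities (eta < eta0, i.e. instrument noise below the
    continuous-phase level) return a *negative* fraction rather than raising,
    so that noisy curves can pass through unharmed.
    """
    arr = np.asarray(eta, dtype=float)
    out = (arr / m.eta0 - 1.0) / m.kE
    return out if out.ndim else float(out)


def laplace_pressure(R, gamma: float):
    """Laplace pressure jump 2*gamma/R across a spherical interface, Pa."""
    arr = np.asarray(R, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("R must be strictly positive")
    if gamma < 0:
        raise DomainError("gamma must be non-negative")
    out = 2.0 * gamma / arr
    return out if out.ndim else float(out)


def kelvin_concentration(R, f: FluidProperties, B_inf: float):
    """Size-dependent equilibrium concentration at a cluster surface.

    B(R) = B_inf * exp(2*gamma*mu / (kB*T*R)): small clusters sustain a higher
    surface concentration, which is the driving asymmetry of Ostwald ripening.
    Strictly decreasing in R with limit ``B_inf`` for a flat interface.
    """
    arr = np.asarray(R, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("R must be strictly positive")
    out = B_inf * np.exp(f.kelvin_length / arr)
    return out if out.ndim else float(out)


def equilibrium_fraction(k1: float, k_minus: float) -> float:
    """Equilibrium dispersed fraction B_inf = k1 / k_minus."""
    if k_minus <= 0:
        raise NoEquilibriumError("k_minus = 0: unbounded growth, no equilibrium")
    return k1 / k_minus


def inflection_time(p: LogisticParams) -> float | None:
    """Time of the sigmoid's inflection, t* = ln((B_inf-B0)/B0)/k1.

    The inflection sits at B = B_inf/2; it falls inside the observation
    window (t* > 0) only for B0 < B_inf/2.  Returns ``None`` otherwise.
    """
    if p.B0 <= 0 or p.k1 <= 0:
        return None
    ratio = (p.B_inf - p.B0) / p.B0
    if ratio <= 1.0:  # B0 >= B_inf/2: inflection at or before t = 0
        return None
    return float(np.log(ratio) / p.k1)
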