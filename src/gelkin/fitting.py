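"""Recover logistic kinetic parameters from viscosity flow curves.

A measured curve eta(t) is fit with the four-parameter reduced logistic

    eta(t) = eta_base + (eta_plateau - eta_base) * sigma(t),
    sigma(t) = (1 - E) / (1 + u * E),      E = exp(-k1 t),  u = (1 - s0)/s0,

which is exactly the Einstein image of the logistic solution B(t) with shape
parameter s0 = B0/B_inf: sigma is the normalized solution pinned to sigma(0)=0,
so eta_base is the *initial* viscosity level and eta_plateau the steady-state
one.  Rising curves (eta_plateau > eta_base, s0 < 1) are undersaturated
starts; falling curves (s0 > 1) are supersaturated relaxations; both branches
are one family.

Only (eta_base, eta_plateau, k1, s0) are identifiable from a curve alone:
the Einstein map confounds eta0*kE with the B scale, so volume-fraction
parameters are reported only when the caller supplies an EinsteinMap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import CurveValidationError, DomainError, FitFailureError
from .kinetics import EinsteinMap, LogisticParams

__all__ = [
    "ViscosityCurve",
    "FitResult",
    "EquilibriumShift",
    "estimate_noise_floor",
    "fit_curve",
    "classify_saturation",
    "gelation_onset_time",
    "equilibrium_shift",
]

UNDERSATURATED = "undersaturated"
SUPERSATURATED = "supersaturated"
FLAT = "flat"


@dataclass
class ViscosityCurve:
    """A sampled Couette viscometry time series.

    t: sample times, s, strictly increasing, >= 4 samples.
    eta: viscosity, mPa·s, non-negative, same length as t.
    meta: acquisition metadata (temperature_C, concentration_pct, rpm, label).
    """

    t: np.ndarray
    eta: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.t.ndim != 1 or self.eta.ndim != 1 or self.t.size != self.eta.size:
            raise CurveValidationError("t and eta must be 1-d arrays of equal length")
        if self.t.size < 4:
            raise CurveValidationError("a curve needs at least 4 samples")
        if np.any(np.diff(self.t) <= 0):
            raise CurveValidationError("times must be strictly increasing")
        if np.any(self.eta < 0):
            raise CurveValidationError("negative viscosities are not physical")

    def __len__(self):
        return self.t.size

    def __eq__(self, other):
        if not isinstance(other, ViscosityCurve):
            return NotImplemented
        return (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.eta, other.eta)
            and self.meta == other.meta
        )


@dataclass
class FitResult:
    """Fitted reduced-logistic description of one flow curve.

    eta_base / eta_plateau: initial and steady-state viscosity levels, mPa·s.
    k1_hat: logistic rate, 1/s.  s0: shape parameter B0/B_inf.
    regime: undersaturated | supersaturated | flat.
    t_onset: gelation onset (sigmoid inflection), s, or None.
    rmse: root-mean-square residual, mPa·s.
    params: volume-fraction LogisticParams when an EinsteinMap was supplied.
    """

    eta_base: float
    eta_plateau: float
    k1_hat: float | None
    s0: float | None
    regime: str
    t_onset: float | None
    rmse: float
    params: LogisticParams | None = None
    diagnostics: dict = field(default_factory=dict)


def reduced_logistic(t, eta_base, eta_plateau, k1, s0):
    """The fitted model: eta_base + (eta_plateau-eta_base) * sigma(t)."""
    t = np.asarray(t, dtype=float)
    E = np.exp(-k1 * t)
    u = (1.0 - s0) / s0
    return eta_base + (eta_plateau - eta_base) * (1.0 - E) / (1.0 + u * E)


def estimate_noise_floor(eta: np.ndarray) -> float:
    """Robust noise scale: 3x the median absolute successive difference."""
    diffs = np.abs(np.diff(np.asarray(eta, dtype=float)))
    return 3.0 * float(np.median(diffs))


def _initial_guess(t, eta):
    """Deterministic derivative-free starting point.

    Base and plateau from the first/last decile means (the base level is the
    *initial* viscosity in this parameterization, so the first decile serves
    both branches); the rate from the maximum slope; the shape parameter from
    the branch sign, refined by a small deterministic multi-start in
    :func:`fit_curve`.
    """
    n = len(eta)
    k = max(3, n // 10)
    start = float(eta[:k].mean())
    end = float(eta[-k:].mean())
    span = end - start
    slope = np.gradient(eta, t)
    k1_0 = 4.0 * float(np.max(np.abs(slope))) / max(abs(span), 1e-12)
    s0_0 = 0.25 if span >= 0 else 2.0
    return start, end, min(max(k1_0, 1e-7), 1.0), s0_0


def fit_curve(
    curve: ViscosityCurve,
    einstein: EinsteinMap | None = None,
    noise_floor: float | None = None,
) -> FitResult:
    """Least-squares reduced-logistic fit of a flow curve.

    Handles both the rising (sigmoid) and falling (supersaturated decay)
    branches.  A curve whose total range does not exceed the noise floor is
    classified ``flat`` without fitting.  Non-convergence raises
    :class:`FitFailureError` carrying the initializer diagnostics.
    """
    t, eta = curve.t, curve.eta
    if noise_floor is None:
        noise_floor = estimate_noise_floor(eta)
    if float(eta.max() - eta.min()) <= noise_floor:
        mean = float(eta.mean())
        return FitResult(
            eta_base=mean,
            eta_plateau=mean,
            k1_hat=None,
            s0=None,
            regime=FLAT,
            t_onset=None,
            rmse=float(eta.std()),
            diagnostics={"noise_floor_mPas": noise_floor},
        )

    base_0, plateau_0, k1_0, s0_0 = _initial_guess(t, eta)

    def residual(x):
        return reduced_logistic(t, x[0], x[1], x[2], x[3]) - eta

    lo = [0.0, 0.0, 1e-9, 1e-5]
    hi = [np.inf, np.inf, 10.0, 1e4]
    rising = plateau_0 >= base_0
    s0_grid = (s0_0,) + ((0.05, 0.45, 0.7) if rising else (1.2, 3.0, 8.0))
    # the slope-based k1 guess degrades when the transition spans only a few
    # samples, so start from several rate scales as well
    k1_grid = (1.0, 0.3, 3.0, 10.0)
    exact_cost = 1e-20 * max(float(np.sum((eta - eta.mean()) ** 2)), 1e-12)
    sol = None
    for s0_try in s0_grid:
        for k1_fac in k1_grid:
            cand = least_squares(
                residual,
                np.array([base_0, plateau_0, min(k1_0 * k1_fac, 10.0), s0_try]),
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=5_000,
            )
            if sol is None or cand.cost < sol.cost:
                sol = cand
            if sol.cost <= exact_cost:
                break  # essentially exact; no need for more starts
        if sol.cost <= exact_cost:
            break
    diagnostics = {
        "init": {"eta_base": base_0, "eta_plateau": plateau_0, "k1": k1_0, "s0": s0_0},
        "status": int(sol.status),
        "nfev": int(sol.nfev),
        "noise_floor_mPas": noise_floor,
    }
    if sol.status <= 0 or not np.all(np.isfinite(sol.x)):
        raise FitFailureError("reduced-logistic fit did not converge", diagnostics)
    eta_base, eta_plateau, k1_hat, s0 = map(float, sol.x)
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    regime = _classify(eta_base, eta_plateau, noise_floor)
    t_onset = _onset(regime, s0, k1_hat)

    params = None
    if einstein is not None:
        try:
            B0 = (eta_base / einstein.eta0 - 1.0) / einstein.kE
            B_inf = (eta_plateau / einstein.eta0 - 1.0) / einstein.kE
            params = LogisticParams.from_equilibrium(k1=k1_hat, B_inf=B_inf, B0=B0)
        except DomainError as exc:
            warnings.warn(f"fitted levels map outside physical fractions: {exc}")
            diagnostics["fraction_conversion_error"] = str(exc)

    return FitResult(
        eta_base=eta_base,
        eta_plateau=eta_plateau,
        k1_hat=k1_hat,
        s0=s0,
        regime=regime,
        t_onset=t_onset,
        rmse=rmse,
        params=params,
        diagnostics=diagnostics,
    )


def _classify(eta_base: float, eta_plateau: float, noise_floor: float) -> str:
    diff = eta_plateau - eta_base
    if diff > noise_floor:
        return UNDERSATURATED
    if diff < -noise_floor:
        return SUPERSATURATED
    return FLAT


def _onset(regime: str, s0: float, k1: float) -> float | None:
    """Inflection time ln((1-s0)/s0)/k1; only inside the window for s0 < 1/2."""
    if regime != UNDERSATURATED or s0 >= 0.5 or k1 <= 0:
        return None
    return float(np.log((1.0 - s0) / s0) / k1)


def classify_saturation(result: FitResult, noise_floor: float) -> str:
    """Regime from the fitted levels: rising beyond the noise floor is
    undersaturated, falling is supersaturated, otherwise flat."""
    return _classify(result.eta_base, result.eta_plateau, noise_floor)


def gelation_onset_time(result: FitResult) -> float | None:
    """Gelation onset: the analytic inflection of the fitted sigmoid.

    Reported only for undersaturated fits whose inflection falls inside the
    observation window (s0 < 1/2, i.e. B0 < B_inf/2); ``None`` otherwise.
    Computed from the fitted form, never from finite differences of raw data.
    """
    if result.k1_hat is None or result.s0 is None:
        return None
    return _onset(result.regime, result.s0, result.k1_hat)


@dataclass(frozen=True)
class EquilibriumShift:
    """Plateau sequence across gelling-mixing cycles and its monotonicity."""

    plateaus: tuple
    non_decreasing: bool


def equilibrium_shift(results: list[FitResult]) -> EquilibriumShift:
    """Report whether fitted plateaus rise across successive stirring cycles.

    Iterating a gelling-mixing-flow history raises the free-monomer level
    and with it the equilibrium fraction, so plateaus should not decrease.
    """
    if len(results) < 2:
        raise DomainError("need at least two successive fits")
    plateaus = tuple(float(r.eta_plateau) for r in results)
    non_dec = all(b >= a for a, b in zip(plateaus, plateaus[1:]))
    return EquilibriumShift(plateaus=plateaus, non_decreasing=non_dec)
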