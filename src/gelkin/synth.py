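"""Synthetic Couette-viscometry curves and rheological-history scenarios.

Emulates the instrument protocol the analysis assumes: 1-h flow curves
sampled every 30 s at 60 or 30 rpm, with additive Gaussian instrument noise.
Four scenario kinds cover the experimental repertoire:

* ``single_curve`` — one logistic curve (sigmoidal rise or supersaturated
  exponential decay depending on B0 vs B_inf);
* ``shear_pair`` — the same dispersion at two shear rates; the reverse
  constant scales with shear (k_minus = c*nu), so the higher-shear curve
  saturates at a proportionally lower plateau;
* ``flow_pause_flow`` — a rise toward B_inf, an at-rest pause during which
  the dispersed fraction grows unbounded (first-order, no shear feedback,
  clamped at b_max), then a resumed flow curve decaying from the now
  supersaturated start back to the same steady state;
* ``gelling_mixing_flow`` — repeated gelling/stirring cycles; each cycle
  raises the free-monomer level A0 and with it B_inf = k_plus*A0/k_minus,
  giving a strictly increasing plateau sequence.

All draws are fixed by the spec seed.  The generators share no code with the
fitting stage beyond the closed forms in :mod:`gelkin.kinetics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError
from .fitting import ViscosityCurve
from .kinetics import (
    EinsteinMap,
    LogisticParams,
    first_order_solution,
    logistic_solution,
    viscosity_from_fraction,
)

__all__ = [
    "ScenarioSpec",
    "PRESETS",
    "preset_spec",
    "generate_curve",
    "generate_shear_pair",
    "generate_flow_pause_flow",
    "generate_gelling_mixing",
    "generate_scenario",
]

_KINDS = ("single_curve", "shear_pair", "flow_pause_flow", "gelling_mixing_flow")


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one synthetic experiment."""

    kind: str
    params: LogisticParams
    einstein: EinsteinMap
    duration: float = 3600.0  # s (1-h protocol)
    dt: float = 30.0  # s sampling step
    noise_sd: float = 0.0  # mPa·s additive Gaussian
    seed: int = 0
    # kind-specific knobs
    pause_duration: float = 3600.0  # s (60 min pause)
    n_cycles: int = 4
    a0_increment: float = 0.10  # fractional A0 increase per stirring cycle
    nu_pair: tuple[float, float] = (2.0 * np.pi, np.pi)  # 60 vs 30 rpm
    start_above: bool = False  # gelling-mixing: start each cycle supersaturated
    b_max: float = 0.9  # ceiling on the unbounded pause growth
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise DomainError(f"unknown scenario kind {self.kind!r}")
        if self.duration / self.dt < 3:
            raise DomainError("duration/dt must yield at least 4 samples")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.n_cycles < 1:
            raise DomainError("n_cycles must be at least 1")
        if not 0 < self.b_max < 1:
            raise DomainError("b_max must be in (0, 1)")

    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.duration + self.dt / 2.0, self.dt)


#: Named parameter presets for the measured conditions.  The kinetic values
#: are invented but documented conveniences (no kinetic constants have been
#: published for agar), chosen so a 1-h curve reaches its steady state.
PRESETS = {
    # 1% agar at 45 degC: undersaturated, sigmoidal rise at 60 rpm
    "agar1_45C": dict(
        params=LogisticParams.from_equilibrium(k1=1e-2, B_inf=0.2, B0=0.02),
        einstein=EinsteinMap(eta0=30.0, kE=2.5),
        noise_sd=0.45,
        meta={"temperature_C": 45.0, "concentration_pct": 1.0, "rpm": 60.0},
    ),
    # 1.5% agar at 50 degC after mixing: supersaturated, exponential decay
    "agar1.5_50C": dict(
        params=LogisticParams.from_equilibrium(k1=1e-2, B_inf=0.2, B0=0.45),
        einstein=EinsteinMap(eta0=30.0, kE=2.5),
        noise_sd=0.45,
        meta={"temperature_C": 50.0, "concentration_pct": 1.5, "rpm": 60.0},
    ),
    # agar 1% + hyaluronic acid 0.5% blend: kinetics identical to the
    # reference (the blend curves overlap the agar-only ones)
    "agar1_hyal0.5_45C": dict(
        params=LogisticParams.from_equilibrium(k1=1e-2, B_inf=0.2, B0=0.02),
        einstein=EinsteinMap(eta0=30.0, kE=2.5),
        noise_sd=0.45,
        meta={"temperature_C": 45.0, "concentration_pct": 1.0, "rpm": 60.0,
              "label": "agar1-hyal0.5 blend"},
    ),
}


def recovery_benchmark_spec(seed: int = 0) -> ScenarioSpec:
    """The parameter-recovery benchmark condition.

    A 1-h/30-s curve whose gelation rise occupies half the viscosity reading
    and is fully resolved by the sampling (inflection mid-window, plateau
    approached by the end): k1 = 2e-3 1/s, B_inf = 0.45, B0 = 0.0225,
    eta0 = 10 mPa·s, kE = 5/2, additive noise 1% of the plateau reading.
    Under these conditions the rate and plateau are statistically
    identifiable to a few percent from a single curve.
    """
    params = LogisticParams.from_equilibrium(k1=2e-3, B_inf=0.45, B0=0.0225)
    einstein = EinsteinMap(eta0=10.0, kE=2.5)
    plateau = einstein.eta0 * (1.0 + einstein.kE * params.B_inf)
    return ScenarioSpec(
        kind="single_curve",
        params=params,
        einstein=einstein,
        noise_sd=0.01 * plateau,
        seed=seed,
    )


def preset_spec(name: str, kind: str = "single_curve", **overrides) -> ScenarioSpec:
    """Build a ScenarioSpec from a named preset, with overrides."""
    if name not in PRESETS:
        raise DomainError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    base = PRESETS[name]
    kwargs = dict(kind=kind, **base)
    kwargs.update(overrides)
    return ScenarioSpec(**kwargs)


def _curve_from_fractions(t, B, spec: ScenarioSpec, rng, label: str) -> ViscosityCurve:
    eta = viscosity_from_fraction(np.asarray(B, dtype=float), spec.einstein)
    if spec.noise_sd > 0:
        eta = eta + rng.normal(0.0, spec.noise_sd, size=eta.shape)
        eta = np.maximum(eta, 0.0)  # the instrument never reports negative
    meta = dict(spec.meta)
    meta.setdefault("label", label)
    return ViscosityCurve(t=np.asarray(t, dtype=float), eta=eta, meta=meta)


def generate_curve(spec: ScenarioSpec) -> ViscosityCurve:
    """One logistic flow curve with seeded additive noise (kind single_curve)."""
    if spec.kind != "single_curve":
        raise DomainError(f"generate_curve needs kind='single_curve', got {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    t = spec.time_grid()
    B = logistic_solution(t, spec.params)
    return _curve_from_fractions(t, B, spec, rng, "single_curve")


def generate_shear_pair(spec: ScenarioSpec) -> tuple[ViscosityCurve, ViscosityCurve]:
    """Two curves at nu_pair shear rates; k_minus scales linearly with nu.

    The first element of nu_pair is the reference at which ``spec.params``
    holds; the second curve has k_minus' = k_minus * nu2/nu1 and therefore
    B_inf' = B_inf * nu1/nu2 — higher shear, lower plateau.
    """
    if spec.kind != "shear_pair":
        raise DomainError(f"generate_shear_pair needs kind='shear_pair', got {spec.kind!r}")
    nu1, nu2 = spec.nu_pair
    if nu1 <= 0 or nu2 <= 0:
        raise DomainError("nu_pair entries must be strictly positive")
    rng = np.random.default_rng(spec.seed)
    t = spec.time_grid()
    curves = []
    for i, nu in enumerate((nu1, nu2)):
        k_minus = spec.params.k_minus * nu / nu1
        p = LogisticParams(
            k1=spec.params.k1, k_minus=k_minus, B0=spec.params.B0
        )
        B = logistic_solution(t, p)
        c = _curve_from_fractions(t, B, spec, rng, f"shear_nu={nu:g}")
        c.meta["nu_per_s"] = float(nu)
        curves.append(c)
    return tuple(curves)


def generate_flow_pause_flow(spec: ScenarioSpec) -> tuple[ViscosityCurve, ViscosityCurve]:
    """Flow, at-rest pause, flow again.

    During the pause the shear feedback is absent (k_minus = 0) and the
    dispersed fraction grows first-order exponentially, clamped at b_max;
    the resumed curve starts supersaturated and relaxes back to the same
    steady state as the initial curve.  Zero pause duration reduces to a
    seamless continuation.
    """
    if spec.kind != "flow_pause_flow":
        raise DomainError(
            f"generate_flow_pause_flow needs kind='flow_pause_flow', got {spec.kind!r}"
        )
    rng = np.random.default_rng(spec.seed)
    t = spec.time_grid()
    p1 = spec.params
    B1 = logistic_solution(t, p1)
    curve1 = _curve_from_fractions(t, B1, spec, rng, "flow_1")
    B_end = float(B1[-1])
    # clamp in log space so extreme pauses cannot overflow the exponential
    if p1.k1 * spec.pause_duration >= np.log(spec.b_max / B_end):
        B_resume = spec.b_max
    else:
        B_resume = first_order_solution(spec.pause_duration, B_end, p1.k1)
    p2 = LogisticParams(k1=p1.k1, k_minus=p1.k_minus, B0=B_resume)
    B2 = logistic_solution(t, p2)
    curve2 = _curve_from_fractions(t, B2, spec, rng, "flow_2_after_pause")
    return curve1, curve2


def generate_gelling_mixing(spec: ScenarioSpec) -> list[ViscosityCurve]:
    """Successive gelling-mixing-flow cycles with rising free-monomer level.

    Cycle c scales A0 by (1 + a0_increment)^c, hence both k1 = k_plus*A0 and
    B_inf = k_plus*A0/k_minus scale identically; the noiseless plateau
    sequence is strictly increasing.  ``start_above`` selects whether each
    cycle starts supersaturated (curves relax top-down) or undersaturated
    (curves rise bottom-up).
    """
    if spec.kind != "gelling_mixing_flow":
        raise DomainError(
            f"generate_gelling_mixing needs kind='gelling_mixing_flow', got {spec.kind!r}"
        )
    if spec.n_cycles < 2:
        raise DomainError("gelling-mixing needs at least 2 cycles")
    rng = np.random.default_rng(spec.seed)
    t = spec.time_grid()
    curves = []
    for c in range(spec.n_cycles):
        factor = (1.0 + spec.a0_increment) ** c
        B_inf_c = spec.params.B_inf * factor
        if not B_inf_c < 1.0:
            raise DomainError("B_inf exceeds 1 after incrementing A0; fewer cycles")
        k1_c = spec.params.k1 * factor
        if spec.start_above:
            B0_c = min(1.5 * B_inf_c, 0.95)
        else:
            B0_c = spec.params.B0
        p = LogisticParams.from_equilibrium(k1=k1_c, B_inf=B_inf_c, B0=B0_c)
        B = logistic_solution(t, p)
        curve = _curve_from_fractions(t, B, spec, rng, f"cycle_{c + 1}")
        curve.meta["cycle"] = c + 1
        curves.append(curve)
    return curves


def generate_scenario(spec: ScenarioSpec) -> list[ViscosityCurve]:
    """Dispatch on spec.kind; always returns a list of curves."""
    if spec.kind == "single_curve":
        return [generate_curve(spec)]
    if spec.kind == "shear_pair":
        return list(generate_shear_pair(spec))
    if spec.kind == "flow_pause_flow":
        return list(generate_flow_pause_flow(spec))
    return generate_gelling_mixing(spec)
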