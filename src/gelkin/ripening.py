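"""Microscopic bounded-ripening-growth particle simulator.

A finite population of spherical clusters exchanges mass with a free-monomer
pool ``A`` (volume fraction) through quasi-static diffusion:

    growth:      4*pi*R^2 dR/dt = mu_eff * J,   J = 4*pi*R*D*(A - B_s(R)),

with ``B_s(R)`` the Kelvin surface concentration (small clusters sit at higher
surface concentration, so when the pool falls between two clusters' surface
levels the small one shrinks and the large one grows — Ostwald ripening).
Two instabilities bound the growth:

* clusters below ``R_dissolve`` are unstable at their Laplace pressure and
  dissolve outright, returning their volume to the pool;
* clusters whose Weber number (computed with the instantaneous Einstein
  viscosity of the dispersion) exceeds the fission threshold break into two
  volume-conserving daughters — symmetric halves by default, or an
  asymmetric split drawn from the seeded generator.

The macroscopic dispersed fraction ``B_total(t)`` that emerges from this
mechanism is sigmoidal and is fit by the closed-form logistic of
:mod:`gelkin.kinetics` (``fit_emergent_logistic``); before the first fission
event the growth is exponential to good approximation.

Mass (``A`` plus the summed cluster fractions) is conserved to round-off by
construction: every radius update debits/credits the pool by the exact volume
change.  Trajectories are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, FitFailureError, MassBalanceError
from .kinetics import (
    EinsteinMap,
    FluidProperties,
    LogisticParams,
    kelvin_concentration,
    logistic_solution,
)
from .weber import critical_radius

__all__ = [
    "ParticlePopulation",
    "SimConfig",
    "Trajectory",
    "standard_fluid",
    "standard_config",
    "init_population",
    "surface_concentration",
    "growth_rate",
    "step",
    "run",
    "fit_emergent_logistic",
    "fit_early_exponential",
]

_FOUR_THIRDS_PI = 4.0 * np.pi / 3.0
# Explicit-Euler substep caps: no radius moves more than this relative amount
# in one substep, preventing sign changes and overshoot of the stiff 1/R flux.
_MAX_REL_DR = 0.1
_MAX_SUBSTEPS = 200_000


@dataclass
class ParticlePopulation:
    """Cluster radii plus the free-monomer pool.

    ``number_scale`` is the number of physical clusters per unit volume that
    each array entry represents (fixed at initialization so that the starting
    cluster fraction equals the configured ``b_init``); it converts radii to
    volume fractions: fraction_i = number_scale * (4/3) pi R_i^3.
    """

    radii: np.ndarray
    A: float
    number_scale: float
    t: float = 0.0

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii <= 0):
            raise DomainError("all radii must be strictly positive")
        if self.A < 0:
            raise DomainError("monomer fraction A must be non-negative")

    def volume_fractions(self) -> np.ndarray:
        return self.number_scale * _FOUR_THIRDS_PI * self.radii**3

    @property
    def B_total(self) -> float:
        return float(self.volume_fractions().sum())

    @property
    def total_mass(self) -> float:
        """Conserved quantity: pool plus dispersed fractions."""
        return self.A + self.B_total


@dataclass(frozen=True)
class SimConfig:
    """Simulation configuration; ``seed`` fixes every stochastic draw."""

    fluid: FluidProperties
    nu: float  # applied shear rate, 1/s
    dt: float = 5.0
    t_end: float = 3600.0
    n_init: int = 200
    R_init: float = 1.4e-7  # initial radius scale, m (lognormal median)
    r_sigma: float = 0.04  # lognormal sigma of initial radii
    seed: int = 0
    breakup_mode: str = "symmetric"  # or "asymmetric"
    asym_range: tuple[float, float] = (0.25, 0.75)  # volume-split draw range
    record_every: float = 10.0
    a_init: float = 0.08  # initial free-monomer volume fraction
    b_init: float = 0.005  # initial total cluster volume fraction
    a_eq: float = 0.02  # flat-interface monomer solubility (Kelvin B_inf)
    mu_eff: float = 1.0  # volume-conversion factor of the Voorhees flux
    kE: float = 2.5
    wi_threshold: float = 1.0  # fission when We exceeds this (We - Wi > 0)

    def __post_init__(self):
        if self.dt <= 0 or self.t_end < self.dt:
            raise DomainError("need dt > 0 and t_end >= dt")
        if self.n_init < 0:
            raise DomainError("n_init must be non-negative")
        if self.breakup_mode not in ("symmetric", "asymmetric"):
            raise DomainError(f"unknown breakup_mode {self.breakup_mode!r}")
        if self.nu < 0:
            raise DomainError("nu must be non-negative")

    @property
    def einstein(self) -> EinsteinMap:
        return EinsteinMap(eta0=self.fluid.eta0, kE=self.kE)


def standard_fluid() -> FluidProperties:
    """Reference dispersion: hydrogel microclusters in a dilute agar sol.

    Interfacial tension of the water-rich cluster/medium interface is
    ultralow (1e-7 N/m, typical of aqueous biopolymer two-phase systems);
    the aggregating unit is a coarse-grained double-helix bundle
    (mu = 1e-22 m^3) with an effective diffusivity 3e-16 m²/s reflecting the
    crowded near-gel medium; T = 318 K (45 degC protocol).
    """
    return FluidProperties(
        eta0=10.0,  # mPa·s
        gamma=1e-7,  # N/m
        D=3e-16,  # m^2/s
        mu=1e-22,  # m^3
        T=318.15,  # K
        delta_rho=20.0,  # kg/m^3
        R_dissolve=7e-9,  # m, = 0.05 * R_init
    )


def standard_config(seed: int = 0, nu: float = 100.0, **overrides) -> SimConfig:
    """The standard bounded-ripening configuration (moderate shear)."""
    kwargs = dict(fluid=standard_fluid(), nu=nu, seed=seed)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def init_population(cfg: SimConfig) -> ParticlePopulation:
    """Seeded lognormal population with total cluster fraction b_init."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_init == 0:
        return ParticlePopulation(
            radii=np.empty(0), A=cfg.a_init, number_scale=0.0, t=0.0
        )
    radii = cfg.R_init * np.exp(rng.normal(0.0, cfg.r_sigma, size=cfg.n_init))
    scale = cfg.b_init / float((_FOUR_THIRDS_PI * radii**3).sum())
    return ParticlePopulation(radii=radii, A=cfg.a_init, number_scale=scale, t=0.0)


def surface_concentration(R, f: FluidProperties, B_inf: float):
    """Kelvin concentration at the cluster surface (delegates to kinetics)."""
    return kelvin_concentration(R, f, B_inf)


def growth_rate(R, A: float, f: FluidProperties, B_inf: float, mu_eff: float = 1.0):
    """Radial growth rate dR/dt = mu_eff * D * (A - B_s(R)) / R, m/s.

    Quasi-static diffusion flux onto an isolated sphere, J = 4*pi*R*D*(A-B_s),
    inserted into the Voorhees mass balance 4*pi*R^2 dR/dt = mu_eff*J.
    Positive exactly when the pool exceeds the Kelvin surface concentration.
    """
    arr = np.asarray(R, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("R must be strictly positive")
    if A < 0:
        raise DomainError("A must be non-negative")
    out = mu_eff * f.D * (A - surface_concentration(arr, f, B_inf)) / arr
    return out if out.ndim else float(out)


def _integrate_radii(radii, A, cfg: SimConfig, number_scale, dt):
    """Advance radii by dt with substepped explicit Euler, conserving mass.

    Returns (radii, A).  Clusters falling below R_dissolve mid-integration are
    dissolved immediately (their remaining volume credited to the pool) — the
    vanishing-radius flux is stiff and not worth resolving.
    """
    f = cfg.fluid
    vol = lambda r: number_scale * _FOUR_THIRDS_PI * r**3
    remaining = dt
    for _ in range(_MAX_SUBSTEPS):
        if remaining <= 0 or radii.size == 0:
            break
        rate = growth_rate(radii, A, f, cfg.a_eq, cfg.mu_eff)
        with np.errstate(divide="ignore"):
            cap = np.where(rate != 0, _MAX_REL_DR * radii / np.abs(rate), np.inf)
        h = min(remaining, float(cap.min()))
        for _halving in range(80):
            new_radii = radii + rate * h
            dB = float((vol(new_radii) - vol(radii)).sum())
            if A - dB >= 0 or h <= 0:
                break
            h *= 0.5  # pool would be overdrawn: shrink the substep
        A -= dB
        if A < -1e-12:
            raise MassBalanceError(f"monomer pool went negative: A={A}")
        A = max(A, 0.0)
        radii = new_radii
        small = radii < max(f.R_dissolve, 0.0)
        if np.any(small):
            A += float(vol(radii[small]).sum())
            radii = radii[~small]
        remaining -= h
    else:
        raise MassBalanceError("substep limit exceeded (stiff configuration)")
    return radii, A


def _fission(radii, cfg: SimConfig, eta_mPas: float, rng) -> np.ndarray:
    """Split every cluster with We > wi_threshold; cascade until none remain.

    Volume is conserved exactly.  Symmetric mode: daughters R * 2^(-1/3)
    (dumbbell fission); asymmetric mode: a volume split drawn once per event
    from the seeded generator (pear-shape fission).
    """
    # We > thr  <=>  R > thr * R*  with R* the critical (We = 1) radius
    r_star = critical_radius(eta_mPas, cfg.nu, cfg.fluid.gamma) if cfg.nu > 0 else np.inf
    r_break = cfg.wi_threshold * r_star
    if not np.isfinite(r_break):
        return radii
    while True:
        over = radii > r_break
        if not np.any(over):
            return radii
        parents = radii[over]
        keep = radii[~over]
        if cfg.breakup_mode == "symmetric":
            daughters = np.repeat(parents * 2.0 ** (-1.0 / 3.0), 2)
        else:
            phi = rng.uniform(*cfg.asym_range, size=parents.size)
            daughters = np.concatenate(
                [parents * phi ** (1.0 / 3.0), parents * (1.0 - phi) ** (1.0 / 3.0)]
            )
        radii = np.concatenate([keep, daughters])


def step(pop: ParticlePopulation, cfg: SimConfig, rng=None) -> ParticlePopulation:
    """One mechanism cycle: ripen over dt, dissolve sub-critical, fission super-critical.

    Mass A + sum(B_i) is conserved across the step to round-off.  ``rng`` is
    only consulted in asymmetric breakup mode; pass the generator threaded by
    :func:`run` for reproducible trajectories.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    radii, A = _integrate_radii(
        pop.radii.copy(), pop.A, cfg, pop.number_scale, cfg.dt
    )
    # dissolution pass (mid-integration dissolution already handled; this
    # catches radii that ended the interval below threshold)
    vol = lambda r: pop.number_scale * _FOUR_THIRDS_PI * r**3
    small = radii < cfg.fluid.R_dissolve
    if np.any(small):
        A += float(vol(radii[small]).sum())
        radii = radii[~small]
    B = float(vol(radii).sum())
    eta = cfg.einstein.eta0 * (1.0 + cfg.einstein.kE * min(B, 1.0))
    radii = _fission(radii, cfg, eta, rng)
    return ParticlePopulation(
        radii=radii, A=A, number_scale=pop.number_scale, t=pop.t + cfg.dt
    )


@dataclass
class Trajectory:
    """Recorded time series of a simulation run."""

    t: np.ndarray  # s
    A: np.ndarray  # monomer fraction
    B_total: np.ndarray  # dispersed fraction
    n_clusters: np.ndarray
    R_mean: np.ndarray  # m
    R_max: np.ndarray  # m
    final_radii: np.ndarray  # m, the ensemble histogram's raw material
    config: SimConfig | None = None

    def __len__(self):
        return self.t.size

    def radius_histogram(self, bins: int = 30):
        """Empirical cluster-size distribution of the final state."""
        return np.histogram(self.final_radii, bins=bins)

    def first_fission_index(self) -> int | None:
        """Index of the first record after the cluster count first rises."""
        n0 = self.n_clusters[0]
        idx = np.nonzero(self.n_clusters > n0)[0]
        return int(idx[0]) if idx.size else None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.t,
                "A_fraction": self.A,
                "B_fraction": self.B_total,
                "n_clusters": self.n_clusters,
                "R_mean_m": self.R_mean,
                "R_max_m": self.R_max,
            }
        )

    def write_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


def run(cfg: SimConfig) -> Trajectory:
    """Run the simulator from the seeded initial population to t_end.

    Records every ``record_every`` seconds (including t = 0).  Deterministic
    given the config, including its seed.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # draws for asymmetric splits
    pop = init_population(cfg)
    rec_t, rec_A, rec_B, rec_n, rec_rm, rec_rx = [], [], [], [], [], []

    def record(p: ParticlePopulation):
        rec_t.append(p.t)
        rec_A.append(p.A)
        rec_B.append(p.B_total)
        rec_n.append(p.radii.size)
        rec_rm.append(float(p.radii.mean()) if p.radii.size else np.nan)
        rec_rx.append(float(p.radii.max()) if p.radii.size else np.nan)

    record(pop)
    n_steps = int(round(cfg.t_end / cfg.dt))
    next_record = cfg.record_every
    for _ in range(n_steps):
        pop = step(pop, cfg, rng)
        if pop.t + 1e-9 >= next_record:
            record(pop)
            next_record += cfg.record_every
    return Trajectory(
        t=np.array(rec_t),
        A=np.array(rec_A),
        B_total=np.array(rec_B),
        n_clusters=np.array(rec_n),
        R_mean=np.array(rec_rm),
        R_max=np.array(rec_rx),
        final_radii=pop.radii.copy(),
        config=cfg,
    )


def fit_emergent_logistic(traj: Trajectory) -> tuple[LogisticParams, float]:
    """Least-squares logistic fit to the emergent B_total(t).

    Returns the fitted :class:`LogisticParams` and the root-mean-square
    residual (fraction units).  Requires a rising trajectory of at least 20
    samples; otherwise raises :class:`FitFailureError` with diagnostics.
    """
    from scipy.optimize import curve_fit

    t, B = traj.t, traj.B_total
    if len(traj) < 20:
        raise FitFailureError(
            "need >= 20 samples", {"n_samples": int(len(traj))}
        )
    rise = B[-1] - B[0]
    if rise <= 0 or rise < 0.05 * max(B.max(), 1e-30):
        raise FitFailureError(
            "trajectory is not rising", {"B_first": float(B[0]), "B_last": float(B[-1])}
        )

    def model(tt, k1, B0, B_inf):
        return B_inf / (1.0 + ((B_inf - B0) / B0) * np.exp(-k1 * tt))

    B_inf0 = float(B[int(0.9 * len(B)):].mean())
    B00 = max(float(B[0]), 1e-12)
    slope = float(np.max(np.gradient(B, t)))
    k10 = max(4.0 * slope / max(B_inf0, 1e-12), 1e-8)
    try:
        popt, _ = curve_fit(
            model,
            t,
            B,
            p0=[k10, B00, B_inf0],
            bounds=([0, 1e-15, 1e-12], [np.inf, 1.0, 1.0]),
            maxfev=20_000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise FitFailureError(str(exc), {"p0": [k10, B00, B_inf0]}) from exc
    k1, B0, B_inf = map(float, popt)
    rmse = float(np.sqrt(np.mean((model(t, *popt) - B) ** 2)))
    params = LogisticParams.from_equilibrium(k1=k1, B_inf=B_inf, B0=min(B0, 1 - 1e-12))
    return params, rmse


def fit_early_exponential(
    traj: Trajectory, end_index: int | None = None
) -> tuple[float, float, float]:
    """Fit log(B_total) vs t on the pre-fission window by linear least squares.

    Returns (k1, B0, r_squared).  ``end_index`` defaults to the first record
    after fission begins (whole trajectory if none occurred).
    """
    if end_index is None:
        end_index = traj.first_fission_index()
    t = traj.t[:end_index]
    B = traj.B_total[:end_index]
    if t.size < 3:
        raise FitFailureError("pre-fission window too short", {"n": int(t.size)})
    y = np.log(B)
    k1, logB0 = np.polyfit(t, y, 1)
    resid = y - (k1 * t + logB0)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return float(k1), float(np.exp(logB0)), r2
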