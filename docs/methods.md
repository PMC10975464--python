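# Methods

## The model

`gelkin` treats the onset of gelation in agar(ose) solutions as the kinetics
of a dispersed phase of growing microgel clusters in a sheared Couette cell.
Three closed-form ingredients define the macroscopic picture:

**Bounded (logistic) kinetics.** The volume fraction `B` of the dispersed
cluster phase obeys

    dB/dt = k1·B − k₋·B² ,

an autocatalytic growth law (rate `k1`, which absorbs the free-monomer
concentration `A0`: `k1 = k₊·A0`) with a shear-controlled negative feedback
`k₋`.  Its solution is the logistic sigmoid

    B(t) = B∞ / (1 + ((B∞ − B0)/B0)·exp(−k1 t)),   B∞ = k1/k₋ ,

rising for an undersaturated start (`B0 < B∞`) and decaying exponentially
for a supersaturated one (`B0 > B∞`).  `B0 = 0` is the degenerate absorbing
state; the formula is undefined there and the code raises a typed error
rather than dividing by zero.  The pure exponential `B0·exp(k1 t)` is the
zero-feedback limit, used for at-rest pause phases.

**Einstein viscosity map.** For a dilute dispersion the measured viscosity
is affine in the dispersed fraction, `η = η0·(1 + kE·B)` with `kE = 5/2` for
spheres.  Volume fraction and (unit-density) mass concentration are
identified.  The inverse map flags sub-baseline readings (`η < η0`,
instrument noise) by returning a negative fraction instead of raising.

**Capillarity.** Clusters are spheres with Laplace pressure `Δp = 2γ/R`.
The equilibrium monomer concentration at a cluster surface follows the
Kelvin relation `B_s(R) = B∞·exp(2γμ/(kB·T·R))`: the exponent is written
with `μ` as a *molecular* (coarse-grained unit) volume in m³ paired with the
Boltzmann constant, the dimensionally consistent reading of the formula;
with a molar volume one would use the gas constant instead.

## Dimensionless equilibrium analysis

A cluster rotating in simple shear (angular velocity `ω = ν/2`, independent
of size) is stable while surface tension beats the shear stress `τ = ην`.
The balance is the Weber number

    We = R·η·ν / (2γ) ,

unity at the hydrostatic-balance radius `R* = 2γ/(ην)`.  Against the
kinetic ratio `Wi = k₋/k₊ = A0/B∞` the single criterion `We − Wi = 0`
separates three regimes: growth-dominated (`We < Wi`: small particles or low
shear), equilibrium, breakup-dominated (`We > Wi`).  Equality is decided
within a configurable band `eps` (default 1e−9, intended for analytic
inputs; widen it for fitted quantities).  Viscosities enter the API in
mPa·s — the instrument convention used throughout — and are converted to
Pa·s internally.

The rpm→shear-rate conversion uses a single `geometry_factor` (default 1,
i.e. the raw angular frequency 2π·rpm/60).  Couette cylinder radii are not
modelled, so only *ratios* of shear rates are quantitatively meaningful; all
analyses use the 60:30 rpm = 2:1 ratio, never absolute shear rates.

## The particle simulator

The microscopic mechanism is simulated with a finite ensemble of spherical
clusters (radii `R_i`) exchanging mass with a common free-monomer pool `A`
(a volume fraction).  Each array entry represents `number_scale` physical
clusters per unit volume, fixed at initialization so the starting cluster
fraction equals `b_init`; fractions are `number_scale·(4/3)πR³`.

* **Growth/dissolution flux.** Quasi-static diffusion to an isolated
  sphere: `J = 4πR·D·(A − B_s(R))`, the standard mean-field closure of
  Fick's first law, giving `dR/dt = mu_eff·D·(A − B_s(R))/R`.  A cluster
  grows exactly when the pool exceeds its Kelvin surface concentration, so
  in a polydisperse ensemble with `A` between two surface concentrations the
  small cluster shrinks while the large one grows — Ostwald ripening.
* **Dissolution.** Radii below `R_dissolve` (default 0.05·`R_init`) are
  removed outright and their volume credited to the pool.  Resolving the
  vanishing-radius dynamics instead would make the scheme stiff for no
  physical gain, since `dR/dt ∝ 1/R` diverges.
* **Breakup.** After each interval, every cluster with `We > 1` (threshold
  configurable as `wi_threshold`) fissions into two volume-conserving
  daughters, cascading until none remain above threshold.  Symmetric mode
  (default) gives two radii `R·2^(−1/3)`, the dumbbell outcome; asymmetric
  mode draws a volume split from the seeded generator (pear-shaped fission).
  `We` uses the instantaneous Einstein viscosity of the dispersion, not
  `η0`, because the shear stress acts through the bulk.
* **Integration.** Explicit Euler with automatic substepping: no radius may
  change by more than 10% within a substep, and a substep is halved if it
  would overdraw the pool.  Every radius update debits/credits `A` by the
  exact volume change, so `A + ΣB_i` is conserved to round-off (measured
  drift ≲ 1e−15 relative over 1000 steps); a pool below −1e−12 raises a
  hard accounting error.  Trajectories are bitwise reproducible given the
  config (the seed fixes the initial radii and any asymmetric-split draws).
* **No nucleation.** The pool only deposits on existing clusters; an
  initial population must be seeded.

### Standard study configuration

The default `SimConfig`/`standard_fluid()` values define the package's
reference condition — a dilute agar sol at 45 °C under moderate Couette
shear:

| parameter | value | rationale |
|---|---|---|
| η0 | 10 mPa·s | continuous phase, tens of mPa·s instrument range |
| γ | 1e−7 N/m | ultralow water–water (biopolymer two-phase) interfacial tension; the premise that ~100 nm clusters break at viscometer shear rates requires γ in this range |
| μ | 1e−22 m³ | coarse-grained double-helix bundle volume; sets the Kelvin length 2γμ/kBT ≈ 4.6 nm |
| D | 3e−16 m²/s | effective diffusivity of such units in the crowded near-gel medium (Stokes–Einstein with a strongly enhanced microviscosity) |
| T | 318.15 K | the 45 °C protocol |
| ν | 100 1/s | moderate shear; critical radius R* ≈ 1.65e−7 m |
| R_init, r_sigma | 1.4e−7 m, 0.04 | narrow lognormal just below R* |
| a_init, b_init, a_eq | 0.08, 0.005, 0.02 | rich pool, small seed population, flat-interface solubility |
| dt, t_end, record_every | 5 s, 3600 s, 10 s | resolves growth; one instrument hour |

Two choices deserve comment.  First, the population starts *near* the
critical radius.  Diffusion-limited growth is a power law (`B ∝ (R0²+ct)^{3/2}`),
so the early window is exponential only over a limited growth span;
initializing near `R*` keeps the pre-fission span short enough that
`log B_total` is linear to R² ≥ 0.992 while leaving a clear multi-sample
window (fission starts around t ≈ 200–400 s).  Physically this is the
moment when coarsening first meets the shear limit — exactly the regime the
bounded-growth mechanism describes.  Second, the shear response of the
*equilibrated* plateau is small (it enters through `B_s(R*(ν))`, a Kelvin
effect of order 1e−2 relative): at 3600 s the lower-shear run has not fully
converged and the ordering can invert at the 1e−4 level, so the
shear-monotonicity property is evaluated on an equilibrated horizon
(t_end = 7200 s), where doubling ν lowers the plateau for every seed.

With this configuration the emergent `B_total(t)` is sigmoidal and a
logistic fit leaves an RMS residual below 1% of the fitted `B∞` (the test
bound is 5%); the ensemble histogram of radii is the empirical stand-in for
a continuum size-distribution description.

## Flow-curve fitting

Measured curves are fit in viscosity space with the four-parameter reduced
logistic

    η(t) = η_base + (η_plateau − η_base)·σ(t),
    σ(t) = (1 − E)/(1 + u·E),   E = exp(−k1 t),   u = (1 − s0)/s0 ,

which is exactly the Einstein image of the sigmoid with shape `s0 = B0/B∞`;
`σ(0) = 0`, so `η_base` is the *initial* viscosity level and the regime
classification is simply the sign of `η_plateau − η_base` against a noise
floor.  Rising and decaying branches are one family (`s0 < 1` vs `s0 > 1`).
The Einstein map confounds `η0·kE` with the fraction scale, so only
(η_base, η_plateau, k1, s0) are reported from a curve alone; volume-fraction
parameters (`B0`, `B∞`, `k₋`) are derived only when the caller supplies an
`EinsteinMap` — the fit never invents `η0`.

Numerics: trust-region least squares with positivity bounds on `k1` and
`s0`, started from a deterministic derivative-free initializer (first/last
decile means for the levels, 4·max-slope/range for the rate) and a small
fixed multi-start over shape and rate scales; single-start fits stall on
fast decays where `exp(−k1 t)` vanishes beyond the first samples.  On
noiseless curves the recovery is exact to machine precision; the fitted
residual threshold for "essentially exact" terminates the multi-start
early.  A curve whose total range is below the noise floor — default 3× the
median absolute successive difference, a robust scale estimate — is
classified `flat` without fitting.

The gelation onset is reported as the analytic inflection of the *fitted*
sigmoid, `t* = ln((1−s0)/s0)/k1`, defined when `s0 < 1/2` (i.e. `B0 < B∞/2`,
inflection inside the window) and only for undersaturated fits.  Raw
second differences of 30-s-sampled noisy data are unusable at 1% noise,
which is why the onset never comes from finite differences.

### Parameter-recovery benchmark

`recovery_benchmark_spec()` fixes the condition for the statistical
recovery study: `k1 = 2e−3` 1/s, `B∞ = 0.45`, `s0 = 0.05`, `η0 = 10` mPa·s,
`kE = 5/2`, additive Gaussian noise with sd = 1% of the plateau reading,
121 samples at 30 s.  The design is chosen so the protocol actually carries
the information: the rise occupies about half of the reading, the
inflection sits mid-window and the plateau is approached by the end.  The
Cramér–Rao bound for `k1` there is ≈1.5%, so the "within 5% of truth in
≥18/20 seeds" check has real margin; for curves whose dispersed
contribution is only a third of the reading the bound exceeds 5% and no
estimator could pass — recovery quality is a property of the experimental
design, not only of the fitter.

## Synthetic data

The generators emulate the instrument protocol: 1-h curves sampled every
30 s (121 points including t = 0), additive i.i.d. Gaussian noise, all
draws fixed by the spec seed.  Scenario kinds:

* `single_curve` — one logistic curve through the Einstein map;
* `shear_pair` — `k₋ ∝ ν` (the simplest coupling consistent with `τ = ην`
  and the observed trend), so a 2:1 shear ratio gives 1:2 equilibrium
  fractions;
* `flow_pause_flow` — logistic rise, then first-order unbounded growth at
  rest (no shear feedback), clamped at `b_max = 0.9` to keep the dilute
  Einstein map meaningful, then a supersaturated decay to the same steady
  state;
* `gelling_mixing_flow` — each stirring cycle multiplies `A0` by
  `1 + a0_increment` (default +10%), raising `k1` and `B∞` identically, so
  noiseless plateaus increase strictly; `start_above` selects top-down
  relaxation versus bottom-up convergence.

Named presets (`agar1_45C`, `agar1.5_50C`, `agar1_hyal0.5_45C`) carry
invented but documented kinetic values — no kinetic constants for agar have
been published — chosen so a one-hour curve reaches its steady state
(`k1 = 1e−2` 1/s, `B∞ = 0.2`, `η0 = 30` mPa·s, noise 1% of plateau).  The
hyaluronic-blend preset deliberately duplicates the agar kinetics, encoding
the observed overlap of blend and reference curves.  Presets are
conveniences, never ground truth.

What the generators do *not* emulate: instrument quantization (no
resolution is specified for the instrument class), multiplicative or
correlated noise, temperature dependence of `k1` and `γ`, thermal lag, or
drift.  Passing tests therefore demonstrate internal consistency of the
model chain and estimator correctness under the stated noise model — not
agreement with any measured dataset, of which none is bundled.

## I/O conventions

Curves are single-run CSV files: leading `# key: value` metadata lines
(temperature_C, concentration_pct, rpm, label), a mandatory `t_s,eta_mPas`
header, one sample per row.  Numbers are serialized with the
shortest-roundtrip decimal repr, making `read(write(curve)) == curve` exact
at double precision.  Multi-curve scenarios produce numbered files plus a
JSON manifest.  Fit results serialize to JSON with units in the field
names; scenario and simulator configs load from TOML.  The CLI exits 0 on
success, 2 on validation/parse errors, 64 on usage errors; logs go to
stderr, data to files or stdout.

## Known limitations

* The continuum size-distribution equation and the rotating-drop shape
  problem are out of scope; breakup is the Weber criterion with prescribed
  daughter geometry, and the ensemble histogram stands in for the
  distribution function.
* The dilute Einstein map is used at fractions where it is, strictly,
  extrapolated; no crowding correction is applied.
* The equilibrated-plateau shear effect in the simulator is a Kelvin-scale
  signal (~1% relative between ν and 2ν); resolving it needs the longer
  horizon noted above.
* `first_order_solution` is unbounded by design; any ceiling is the
  caller's (scenario code clamps at `b_max`).
* Absolute shear rates, and hence absolute Weber numbers for the instrument,
  depend on an uncalibrated geometry factor; quantitative claims are made
  on ratios only.
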