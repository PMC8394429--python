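# Methods

## The kinetic model

Drying of a nixtamalized corn grain at constant temperature is modelled as
first-order relaxation of its moisture percentage toward equilibrium:

    dM/dt = -k (M - ME),   M(0) = M0,  M(∞) = ME
    M(t) = (M0 - ME) e^{-k t} + ME

The model's assumptions: a single well-mixed moisture pool per grain (no
radial profile), constant temperature, constant k over the drying run, and
a finite equilibrium moisture ME set by the drying air. The moisture
percentage is used on whatever basis (wet or dry) the data carries — the
model is basis-agnostic, and the package documents but does not convert
bases.

Derived quantities:

- dehydration rate `vI = -k (M0 - ME) e^{-kt}` (negative: moisture lost),
  initial rate `v0 = -k (M0 - ME)`;
- moisture ratio `MR = e^{-kt}`;
- time to a target moisture `t = (1/k) ln[(M0 - ME)/(M - ME)]`. A target at
  or below ME raises an error rather than returning +∞: equilibrium is
  approached asymptotically and is unreachable in finite time. The t → ∞
  limits are exposed as explicit asymptote accessors, not sentinel times.

Units: time is minutes internally and k is per minute (drying times are
measured in minutes; hour-based reporting is formatting only). Moisture
and rates are percent and percent/min.

## Fick's-law linkage

For a homogeneous sphere of radius `a` with constant effective diffusivity
`Deff`, the Crank solution of Fick's second law gives the moisture ratio

    MR(t) = (6/π²) Σ_{n≥1} (1/n²) exp(-Deff n² π² t / a²)

Note on the series convention: an alternative printed form with a leading
`1 -` and an alternating `(-1)^n` factor evaluates to 1.5 at t = 0 and is
inconsistent with MR(0) = 1 and with the one-term slope logic below; this
package implements the standard Crank sphere solution, whose one-term
reduction reproduces that slope logic exactly.

Keeping only n = 1 and matching the exponent against the empirical
`MR = e^{-kt}` identifies

    Deff = k a² / π²        k = π² Deff / a²

The default radius is a = 0.0049 m (average corn grain). Deff is stored in
m²/min and reported in m²/h (×60), the conventional unit. The "diffusivity
rate" `vk = dM/dk = -t (M0 - ME) e^{-kt}` — the sensitivity of the drying
curve to k — is implemented in its final closed form; its magnitude has a
unique maximum at t = 1/k.

Numerical evaluation of the series: default truncation at 200 terms with
early exit once a term drops below 1e-12, plus a damped trigamma tail
correction `exp(-(N+1)² τ) ψ₁(N+1)` (τ the dimensionless time). The bare
Basel partial sum at N terms undershoots 1 at t = 0 by ≈ (6/π²)/N ≈ 3e-3
for N = 200; the correction is exact at t = 0 and decays faster than the
last retained term for t > 0, so normalization is exact without changing
any late-time value beyond 1e-12. Bare truncation remains available
(`tail_correction=False`). The one-term reduction is accurate to 0.5 %
only once the dimensionless time exceeds ≈ 1.3 (at τ = 1 its error is
1.23 %); it should not be used early in drying.

## Fitting

`IsothermalDryingModel.fit()` estimates (M0, ME, k) by nonlinear least
squares (scipy `least_squares`, trust-region reflective) on the moisture
curve. Choices that matter:

- Initialization is deterministic and data-driven: M0⁰ = first observed
  moisture, ME⁰ = last observed moisture, k⁰ = magnitude of the log-linear
  slope of ln(M - ME⁰) over the points above ME⁰. No seed dependence.
- Bounds keep the optimizer physical: k ∈ (1e-6, 1) /min, ME ∈ [0, M0⁰],
  M0 ∈ [ME⁰, 100] %.
- Tolerances 1e-12 (ftol/xtol/gtol); up to 3 restarts with multiplicative
  jitter from a fixed internal seed before a convergence error that carries
  the last iterate. Fewer than 4 distinct times, or a constant series, is
  rejected up front.
- R² is the conventional coefficient of determination 1 - SSres/SStot with
  SStot about the observed mean.
- Replicates are averaged per (ST, time) before fitting by default;
  fitting raw replicate points (equal weight) is available via
  `average_replicates=False`, and per-observation weights can be supplied.
  Both paths are provided because either could underlie a published fit.

The log-linear route (`fit_loglinear`) regresses
`ln[(M - ME)/(M_first - ME)]` on t at a fixed ME; the slope magnitude
estimates k and the intercept is 0 on noiseless data. It requires every
observation to exceed ME — in particular the 2600-min equilibrium point
must be excluded, since there the excess M - ME underflows at percent
scale — and is therefore a drying-window (0–120 min) method.

## Synthetic data

The generator emulates the reference experiment: steeping times 0, 2, 4,
6, 8 h; weighings every 15 min over 0–120 min plus one equilibrium point
at 2600 min; five replicates. Generating (k, ME) pairs per steeping time
are the published fitted values (k = 0.0185, 0.0161, 0.0158, 0.0147,
0.0140 /min; ME = 5.088, 5.399, 5.792, 5.646, 5.836 %). No M0 values are
published, so the generator uses a synthetic stand-in profile
(38, 45, 47, 46.5, 46 % for ST = 0, 2, 4, 6, 8), rising steeply from the
cook-only condition toward a ~47 % ceiling and flagged as synthetic in the
dataset sidecar.

Noise is additive Gaussian with standard deviation interpolating from
0.993 % at t = 0 down to 0.181 % at 2600 min, linearly in log(1 + t).
The band endpoints are the reported measurement-uncertainty interval; the
log-time schedule encodes the observation that readings stabilise late in
drying (the exact schedule is this package's choice). Negative draws are
clipped at 0 and flagged in a `clipped` column. Everything is reproducible
from a single integer seed.

What the generator does not emulate: the hydration (uptake) phase, the
cooling profile of the steeping liquor, calcium uptake, replicate-level
systematic offsets (grain-to-grain M0 variation), and any drift of k
within a run. Passing recovery tests therefore show that the pipeline is
correct and well-conditioned at the stated design and noise level — not
that real grain-drying data obey the first-order model; that evidence
comes from the fit quality on real trajectories.

## Surfaces and isolines

Per-ST parameter triples are interpolated across steeping time
component-wise — piecewise linear by default (transparent, and every
interpolated parameter stays within the convex hull of the node values);
shape-preserving monotone cubic (PCHIP) optionally. No extrapolation
beyond the measured ST range [0, 8] h is permitted: nothing in the data
supports it.

Moisture and rate grids default to ST steps of 0.1 h and time steps of
10 min over 0–2600 min (81 × 261) with 14 isoline levels. Isolines are
extracted by marching squares with linear edge interpolation
(scikit-image `find_contours`; saddle ambiguity resolved by that routine's
cell-interpolation convention), then mapped from index space to (ST, t)
coordinates. A requested level outside the grid's value range yields an
empty result with a warning, as does a constant grid at exactly the level
(the degenerate whole-domain case).

## Numerical notes and limitations

- At the published k and the 2600-min equilibrium point, k·t ≈ 48 and the
  moisture excess (M0-ME)e^{-kt} ≈ 1e-20 underflows against the
  percent-scale ME in double precision: the stored moisture equals ME
  exactly. Consequently the percent-level inverse identity
  t(M(t)) = t is numerically meaningful only while the excess is
  representable (k·t ≲ 45); the moisture-ratio form (1/k)·ln(1/MR) is
  exact over the full window. Tests and users should invert through MR
  near equilibrium.
- Applying Deff = k a²/π² with a = 0.0049 m to all five published k values
  gives 2.70, 2.35, 2.31, 2.15, 2.04 ×10⁻⁶ m²/h — only the interior
  steeping times fall inside the commonly quoted 2.26–2.56 ×10⁻⁶ m²/h
  band, whose endpoints do not follow from these k values alone. The
  package reports what the formula gives and asserts the band only where
  it holds (ST = 4 h).
- Time-varying k(t) within a drying run, radial concentration profiles,
  calcium-ion transport, and a Lorentzian model of v0 vs M0 are out of
  scope: no governing equations are available to implement.
- The acceptance script's problem sizes — the full 250-row design for
  fitting, 0.01-min grid steps for the vk peak search — are the package's
  defaults for these analyses and run in seconds.
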