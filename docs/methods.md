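# Methods

This note records the models implemented in `levitrace`, the parameter
choices that matter, the numerical decisions, and what the synthetic-data
generator does and does not emulate.

## Thermal-oscillator model

Each motional axis of the trapped particle is a damped harmonic oscillator
driven by thermal (gas-collision) noise:

    x'' + Γ₀ x' + ω₀² x = sqrt(2 Γ₀ k_B T₀ / m) ξ(t),   ⟨ξ(t)ξ(t')⟩ = δ(t−t').

Its stationary displacement PSD, in the two-sided angular-frequency
normalisation used throughout the package, is

    S_xx(ω) = k_B T₀ Γ₀ / (π m) · 1 / ((ω₀² − ω²)² + ω² Γ₀²),

whose integral over all ω is the equipartition variance k_B T₀/(m ω₀²).
The detector sees v(t) = Σ_axis γ_axis x_axis(t) + n(t), with conversion
factors γ in V/m and white noise n of one-sided density `noise_floor`
(V²/Hz). Spectra are displayed and stored one-sided in Hz; the conversion
(×4π on the density, ×2π on the abscissa) is confined to
`spectral.model_psd_hz` and the data preparation inside
`spectral.fit_lorentzian`.

Gas damping is the free-molecular (Epstein) relation used in inverse form
by the fitting stage:

    Γ₀ = 0.619 · (9π/√2) · η_air d² / (ρ k_B T₀) · P_gas / r.

At the package defaults (75 nm radius, 3.5 mbar, 300 K) this gives
Γ₀/2π ≈ 3.0 kHz. The estimator flags results where the Knudsen number
(mean free path over radius) drops below 10, outside the free-molecular
regime.

## Exact integration of the Langevin dynamics

`simulate.simulate_axis` propagates the state (x, v) with the exact
discrete-time solution of the linear SDE: transition matrix M = exp(A·Δt)
for the drift A = [[0, 1], [−ω₀², −Γ₀]], and per-step Gaussian noise with
covariance Q = Σ_stat − M Σ_stat Mᵀ, where Σ_stat =
diag(k_B T₀/(m ω₀²), k_B T₀/m) is the stationary covariance. Because the
initial state is drawn from Σ_stat, the sampled process is exactly
stationary with the equipartition variance at *any* step size — there is
no integrator bias to tune against. (An Euler–Maruyama scheme would bias
the variance at the percent level at the default step of 1 µs.) The
two-dimensional recursion is evaluated as two complex first-order filters
in the eigenbasis of M (`scipy.signal.lfilter`), so second-long traces at
1 MHz are vectorised. T₀ = 0 yields the zero trajectory.

Aliasing of the sampled process is negligible at the defaults (peaks at
40–140 kHz, linewidth ~3 kHz, Nyquist 500 kHz); configurations with
sample_rate ≤ 4·f₀ are rejected outright.

## Defaults of the synthetic cohorts

The study conditions the generator reproduces: chamber pressure 3.5 mbar,
thermal equilibrium at T₀ = 300 K, three resolved peaks per trace, cohort
sizes of ~64–66 particles, considerable particle-size dispersion.
Quantities the experiment does not fix are declared here once:

| parameter | default | rationale |
|---|---|---|
| nominal radius r | 75 nm | single-beam 1550 nm silica trapping practice |
| silica density ρ | 1850 kg/m³ | amorphous fumed-silica convention |
| silica permittivity (1550 nm) | 2.085 | n = 1.444 |
| air viscosity η_air | 1.81×10⁻⁵ Pa·s | room-temperature air |
| air molecule diameter d | 0.372 nm | kinetic-theory value |
| f1, f2, f3 | 40, 120, 140 kHz | ordered, resolved, below Nyquist/4 |
| sample rate / duration | 1 MHz / 1 s | ≥10⁴ oscillation periods, Δf ≈ 30 Hz at the default Welch segment |
| conversion factors γ | 5×10⁵ V/m per axis | volt-scale traces for nm-scale motion |
| detector noise floor | 10⁻¹² V²/Hz | white, several decades below the peaks |
| radius dispersion | 10 % CV, normal | matches "considerable variance" in particle size |

Class structure: a functionalized class carries per-axis trap-frequency
offsets equal to f_axis · (√((α/m)_coated/(α/m)_bare) − 1), evaluated by
the shift model at the cohort's particle radius — the class effect *is*
the physical mechanism (α/m), not an arbitrary dial. At full monolayer
coverage on a 75 nm sphere the relative shift is ≈1.24 % (adenine) and
≈0.74 % (thymine). The ZnCl₂-concentration series maps concentration to
monolayer coverage {100 µM: 0.35, 500 µM: 0.62, 750 µM: 0.65,
1000 µM: 1.0}; binding increases with concentration and the 500/750 µM
groups are nearly equivalent, mirroring the observed similarity of those
groups.

What the generator does **not** emulate: trap-frequency drift (laser power
or pointing), pressure-gauge error, cross-axis coupling and Duffing
nonlinearity, photon-recoil heating, detector nonlinearity, and particle
asphericity. Synthetic cohorts are therefore *cleaner* than trap data:
with default offsets the three-class cohort classifies at or near accuracy
1.0, where real data plateaued lower. Passing classification tests shows
the chain is statistically sound (chance on null data, perfect on
separated data, monotone in separation), not that any particular real
experiment reaches a given accuracy.

## Fitting stage

Welch estimation uses a Hann window, 2¹⁵-sample segments and 50 % overlap
(Δf ≈ 30.5 Hz at 1 MHz) — enough resolution for a 3 kHz linewidth and
~60 averages per 1-s trace. Peak detection finds the three most prominent
maxima of the smoothed log-spectrum above 5 kHz; each fit window spans
three estimated FWHM either side of its peak (≥6 linewidths total where
neighbours permit), truncated at the midpoint to the next peak. Peaks
closer than `min_separation` trigger a merged-window warning; fewer than
three prominences is an explicit failure listing what was found.

The Lorentzian fit runs in angular frequency with an additive noise-floor
nuisance parameter. Initialisation is deterministic: B from the peak bin,
C from the half-maximum width, A from the on-resonance height, floor from
the window median. Weighting: a first pass with σ ∝ data, then one
reweighted pass with σ ∝ fitted model (Welch estimator errors scale with
the local mean; model weighting removes the bias toward high-power bins
without iterating to a fixed point). A fit is flagged unconverged when the
centre leaves the window or the width exceeds the window span (the
flat-noise signature). Each peak is fitted independently; a joint
three-peak fit would share no parameters under this model and was not
used.

Derived quantities are computed in the acyclic order radius → mass → γ:
the radius from the damping C of the f1 (z-axis) peak by default
(configurable; all three per-peak radii are kept as features, since each
peak's width estimates the same particle in the same gas), the mass from
that radius, and γ = √(A·πm/(C·k_B T₀)) from the same peak's amplitude —
the unique inversion of A's definition, verified exact in the round-trip
tests. Seed-averaged recovery on default cohorts: ω₀ to ≲0.01 %, Γ₀ and
radius to ≲1 %, γ to ≲2 %.

## Outlier screen

A row is removed when |x − median| > 1.5·IQR in any numeric column.
Quartiles use linear interpolation between order statistics (the numpy
default, recorded in the output sidecar). The statistics are computed
once on the input table — a single pass; iterative re-filtering is not
used because it has no deterministic stopping point on heavy-tailed
columns. The filter is global per dataset (a per-class mode exists behind
a flag). Tables with fewer than four rows pass through unchanged with a
warning, since quartiles are undefined. The strict inequality means
constant columns (IQR = 0) remove nothing.

## Classification stage

Features are standardised before UMAP (columns span ~20 orders of
magnitude in SI units); trees are scale-free so the forest uses raw
values. The supervised UMAP (n_neighbors = 50 clamped to n−1 on small
tables, min_dist = 0.0) is a descriptive view of the full labelled dataset
and deliberately not a classifier, so it takes no train/test split.

MCCV draws, per iteration, a fresh stratified 80/20 split (stratification
prevents empty-class training sets on cohorts of ~60 rows; an unstratified
mode exists, with resampling of splits that lose a class), trains a random
forest (default 100 trees, unlimited depth, √p features per split) and
records the unweighted test accuracy, the out-of-bag error, and
impurity-decrease importances normalised to sum to one before averaging.
One master seed spawns all split and forest seeds through
`numpy.random.SeedSequence`, making full runs bit-reproducible. The tuning
grid (trees ∈ {100, 300, 500}, depth ∈ {∞, 5, 10}, features ∈ {√p, p},
optional feature subsets) is evaluated exhaustively at reduced iteration
count; ties break toward fewer features, then fewer trees, then shallower
depth.

## Coating frequency-shift model

In the Rayleigh regime the trap frequency satisfies ω₀² = (α/m)·k_field,
with k_field = 4P/(πε₀c w₀⁴) transverse and I₀/(ε₀c z_R²) axial for a
Gaussian focus — so frequency depends on the particle only through α/m.
The coated particle uses the quasi-static core–shell polarizability
(coated-sphere Clausius–Mossotti), which reduces exactly to
4πε₀r³(ε−1)/(ε+2) at zero shell. A molecular layer of fractional coverage
c is a homogeneous shell of thickness 0.34 nm (the base stacking distance)
whose permittivity follows from the molecular polarizability at number
density c/(footprint·thickness), and whose mass is the molecule count
times the molecular mass. Molecular constants are literature-typical
static values: adenine 13.1 ų by polarizability volume, 135.13 Da;
thymine 11.2 ų, 126.115 Da; footprint 0.25 nm² per flat-lying base. The
ZnCl₂ salt layer is not modelled.

The single-molecule shift is defined as the zero-coverage derivative of
the full coated-sphere result divided by the monolayer molecule count
(evaluated at coverage 10⁻³, well inside the linear regime). This differs
from the naive free-molecule estimate (f/2)(α_mol/α − m_mol/m) by the
local-field factor of the dielectric core, and the implementation keeps
the derivative definition so that the perturbative and full routes agree
— an invariant under test.

The headline estimates are evaluated at a declared reference
configuration — core radius 11.5 nm, beam power 4.35 mW, waist 1.0 µm at
1550 nm — chosen once so that, with the molecular constants above, the
model yields its two quoted scales: ≈1.0 kHz shift per adenine monolayer
and ≈30 mHz for a single adenine-vs-thymine substitution. Both estimates
therefore validate the model *jointly with* these declared constants; the
model itself (all radii, powers, waists, molecules) is general, and the
scenario invariants (zero-shell limit, α/m sufficiency, linearity in
coverage, antisymmetry) hold everywhere.

## Numerical notes and degenerate inputs

* Per-step noise covariance Q is symmetrised and its eigenvalues clipped
  at zero before factorisation (Q is PSD analytically; roundoff can leave
  it indefinite at the 10⁻³⁰ level).
* Critically damped axes (Γ₀ = 2ω₀) make the propagator eigenbasis
  singular; physically relevant traps are far underdamped (Q ≈ 100 at
  3.5 mbar) and the package does not special-case that measure-zero point.
* `estimate_psd` rejects segments longer than the trace and overlaps
  outside [0, 1); `fit_lorentzian` requires ≥10 bins per window.
* Importance vectors of degenerate forests (all-zero importances) fall
  back to uniform so per-iteration normalisation is always defined.
* Problem sizes in the test suite and acceptance script (20 seeds × 1 s
  traces; 30-particle recovery cohorts; 300-iteration MCCV on cohorts of
  45–66 rows) were chosen to put Monte-Carlo error well below the stated
  tolerances while keeping a full run to minutes on one CPU.

## Known limitations

* The harmonic, axis-decoupled model omits Duffing nonlinearities and
  cross-axis coupling that real traps show at large amplitude.
* The calibration assumes T₀ is known; γ and radius errors are inherited
  by mass (∝ r³) and are correlated across features of one particle.
* The Epstein inversion degrades outside the free-molecular regime
  (flagged via Knudsen number) and assumes spherical particles.
* UMAP coordinates are descriptive; distances between clusters carry no
  calibrated meaning and are seed-dependent up to isometry.
* The shift model is quasi-static (Rayleigh); Mie corrections, absorption
  and heating are out of scope, as is the salt layer.
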