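"""Langevin synthetic-data generator for an optically levitated nanoparticle.

The detector channel of a levitated-optomechanics experiment carries the
thermal motion of the trapped particle along three axes (z, x, y), seen as
three Lorentzian peaks f1 < f2 < f3 in the power spectral density. This
module reproduces that signal from first principles: each axis is a damped
harmonic oscillator driven by thermal noise,

    x'' + Gamma0 x' + omega0^2 x = sqrt(2 Gamma0 kB T0 / m) * xi(t),

whose stationary displacement PSD is the thermal-oscillator Lorentzian with
two-sided angular-frequency normalisation

    S_xx(omega) = kB T0 Gamma0 / (pi m) / ((omega0^2-omega^2)^2 + omega^2 Gamma0^2),

so the variance integrates to the equipartition value kB T0 / (m omega0^2).
The gas damping rate Gamma0 follows from pressure and particle radius in the
free-molecular (Epstein) regime, using the same relation the fitting stage
inverts to estimate the radius.

Integration uses the exact discrete-time update of the Ornstein–Uhlenbeck
driven oscillator (matrix-exponential propagator with exact covariance
propagation), so equipartition holds at any step size; there is no
discretisation bias for acceptance-style statistics.

Cohorts of particles with per-particle radius dispersion and class-dependent
trap-frequency offsets stand in for the experiment's particle groups
(standard silica vs oligonucleotide-functionalized).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.linalg import expm

from .constants import (
    D_AIR,
    ETA_AIR,
    KB,
    MBAR_TO_PA,
    RHO_SILICA,
    T_ENV,
)
from . import shiftmodel

__all__ = [
    "TrapParams",
    "ParticleSpec",
    "TimeTrace",
    "damping_rate",
    "simulate_axis",
    "synthesize_trace",
    "generate_cohort",
    "default_class_specs",
    "concentration_series_specs",
    "save_trace_hdf5",
    "load_trace_hdf5",
    "save_trace_csv",
    "write_manifest",
]

#: Default axis frequencies f1, f2, f3 (Hz) for z, x, y.
DEFAULT_FREQS = (40e3, 120e3, 140e3)
#: Default detector conversion factors (V/m) per axis.
DEFAULT_CONV = (5e5, 5e5, 5e5)
#: Default white detector-noise density (V^2/Hz, one-sided).
DEFAULT_NOISE_FLOOR = 1e-12
#: Default chamber pressure (mbar) at which traces are recorded.
DEFAULT_PRESSURE_MBAR = 3.5
#: Default nominal particle radius (m).
DEFAULT_RADIUS = 75e-9

_AXES = ("z", "x", "y")


def damping_rate(
    radius: float,
    pressure: float,
    temperature: float = T_ENV,
    density: float = RHO_SILICA,
    eta_air: float = ETA_AIR,
    d_air: float = D_AIR,
) -> float:
    """Gas damping rate Gamma0 (rad/s) in the free-molecular regime.

    This is the exact inverse of the radius estimator
    ``r = 0.619 * (9 pi / sqrt(2)) * eta d^2 / (rho kB T0) * P / Gamma0``,
    so radius -> Gamma0 -> radius round-trips identically.

    Parameters use SI units; ``pressure`` is in Pa.
    """
    if radius <= 0 or pressure <= 0:
        raise ValueError("radius and pressure must be positive")
    k = 0.619 * 9.0 * math.pi / math.sqrt(2.0) * eta_air * d_air**2 / (
        density * KB * temperature
    )
    return k * pressure / radius


@dataclass(frozen=True)
class ParticleSpec:
    """A particle to simulate: geometry, material and class identity.

    ``freq_offsets`` are per-axis additive trap-frequency offsets in Hz that
    encode the effect of a surface coating on alpha/m (the trap frequency
    changes; the damping, set by geometry and gas, does not). They must be
    zero for the unfunctionalized ``"standard"`` class.
    """

    radius: float = DEFAULT_RADIUS
    density: float = RHO_SILICA
    class_label: str = "standard"
    freq_offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.density <= 0:
            raise ValueError("radius and density must be positive")
        if self.class_label == "standard" and any(self.freq_offsets):
            raise ValueError("standard particles carry no frequency offsets")

    @property
    def mass(self) -> float:
        """Spherical-particle mass (4/3) pi r^3 rho (kg)."""
        return 4.0 / 3.0 * math.pi * self.radius**3 * self.density


@dataclass(frozen=True)
class TrapParams:
    """Per-axis oscillator parameters of one trapped particle.

    Angular frequencies are in rad/s; ``pressure`` is in Pa. ``gamma0`` is
    shared by the axes (one particle, one gas environment).
    """

    omega0_z: float
    omega0_x: float
    omega0_y: float
    gamma0: float
    mass: float
    temperature: float = T_ENV
    conv_z: float = DEFAULT_CONV[0]
    conv_x: float = DEFAULT_CONV[1]
    conv_y: float = DEFAULT_CONV[2]
    noise_floor: float = DEFAULT_NOISE_FLOOR
    pressure: float = DEFAULT_PRESSURE_MBAR * MBAR_TO_PA

    def __post_init__(self) -> None:
        if min(self.omega0_z, self.omega0_x, self.omega0_y) <= 0:
            raise ValueError("angular frequencies must be positive")
        if self.gamma0 <= 0 or self.mass <= 0 or self.temperature < 0:
            raise ValueError("gamma0 and mass must be positive, temperature >= 0")
        omegas = (self.omega0_z, self.omega0_x, self.omega0_y)
        if len({round(w, 9) for w in omegas}) < 3:
            raise ValueError("axis frequencies must be pairwise distinct")

    @property
    def omegas(self) -> tuple[float, float, float]:
        return (self.omega0_z, self.omega0_x, self.omega0_y)

    @property
    def convs(self) -> tuple[float, float, float]:
        return (self.conv_z, self.conv_x, self.conv_y)

    @classmethod
    def from_particle(
        cls,
        particle: ParticleSpec,
        pressure_mbar: float = DEFAULT_PRESSURE_MBAR,
        temperature: float = T_ENV,
        base_freqs: tuple[float, float, float] = DEFAULT_FREQS,
        conv: tuple[float, float, float] = DEFAULT_CONV,
        noise_floor: float = DEFAULT_NOISE_FLOOR,
        eta_air: float = ETA_AIR,
        d_air: float = D_AIR,
    ) -> "TrapParams":
        """Build trap parameters for a particle at a given chamber pressure.

        The damping rate comes from the pressure and the particle's radius
        through the free-molecular relation; the class frequency offsets are
        added to the base axis frequencies.
        """
        pressure = pressure_mbar * MBAR_TO_PA
        gamma0 = damping_rate(
            particle.radius, pressure, temperature, particle.density, eta_air, d_air
        )
        freqs = [f + df for f, df in zip(base_freqs, particle.freq_offsets)]
        return cls(
            omega0_z=2.0 * math.pi * freqs[0],
            omega0_x=2.0 * math.pi * freqs[1],
            omega0_y=2.0 * math.pi * freqs[2],
            gamma0=gamma0,
            mass=particle.mass,
            temperature=temperature,
            conv_z=conv[0],
            conv_x=conv[1],
            conv_y=conv[2],
            noise_floor=noise_floor,
            pressure=pressure,
        )


@dataclass
class TimeTrace:
    """A single detector time trace plus its experiment metadata."""

    sample_rate: float
    samples: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


def simulate_axis(
    omega0: float,
    gamma0: float,
    mass: float,
    temperature: float,
    duration: float,
    sample_rate: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate the displacement (m) of one thermally driven axis.

    Exact discretisation: the state (x, v) is propagated with the matrix
    exponential of the drift and per-step noise of covariance
    ``Sigma_stat - M Sigma_stat M^T``, which makes the sampled process
    exactly stationary with the equipartition covariance at any step size.
    The recursion is evaluated with two complex first-order filters
    (eigenbasis of the propagator), so long traces are vectorised.
    """
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    if omega0 <= 0 or gamma0 <= 0 or mass <= 0 or temperature < 0:
        raise ValueError("omega0, gamma0, mass must be positive; temperature >= 0")
    f0 = omega0 / (2.0 * math.pi)
    if sample_rate <= 4.0 * f0:
        raise ValueError(
            f"sample_rate {sample_rate:g} Hz undersamples the oscillator at "
            f"{f0:g} Hz (need > 4x the natural frequency)"
        )
    if duration < 100.0 * (2.0 * math.pi / omega0):
        warnings.warn(
            "trace shorter than 100 oscillation periods; spectral estimates "
            "will be poorly resolved",
            stacklevel=2,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    if temperature == 0.0:
        return np.zeros(n)
    dt = 1.0 / sample_rate
    drift = np.array([[0.0, 1.0], [-(omega0**2), -gamma0]])
    prop = expm(drift * dt)
    sig_stat = np.diag([KB * temperature / (mass * omega0**2), KB * temperature / mass])
    q = sig_stat - prop @ sig_stat @ prop.T
    q = 0.5 * (q + q.T)
    evals, evecs = np.linalg.eigh(q)
    noise_l = evecs * np.sqrt(np.clip(evals, 0.0, None))
    x0 = np.linalg.cholesky(sig_stat) @ rng.standard_normal(2)
    steps = rng.standard_normal((n, 2)) @ noise_l.T
    lam, vmat = np.linalg.eig(prop)
    y0 = np.linalg.solve(vmat, x0)
    eta = np.linalg.solve(vmat, steps.T)
    y = np.empty((2, n), dtype=complex)
    for k in range(2):
        y[k], _ = signal.lfilter(
            [1.0], [1.0, -lam[k]], eta[k], zi=np.array([lam[k] * y0[k]])
        )
    return (vmat @ y).real[0]


def synthesize_trace(
    particle: ParticleSpec,
    trap: TrapParams,
    duration: float = 1.0,
    sample_rate: float = 1e6,
    seed: int = 0,
) -> TimeTrace:
    """Synthesize the single detector channel for one trapped particle.

    The voltage is the conversion-weighted sum of the three axis
    displacements plus white Gaussian detector noise at the configured
    one-sided density. Ground-truth parameters are stored in the metadata so
    downstream recovery can be scored.
    """
    ss = np.random.SeedSequence(seed)
    axis_ss, noise_ss = ss.spawn(2)
    axis_rngs = [np.random.default_rng(s) for s in axis_ss.spawn(3)]
    n = int(round(duration * sample_rate))
    volts = np.zeros(n)
    overlap_warning = False
    omegas = trap.omegas
    for i in range(3):
        for j in range(i + 1, 3):
            if abs(omegas[i] - omegas[j]) < 3.0 * trap.gamma0:
                overlap_warning = True
    if overlap_warning:
        warnings.warn(
            "axis peaks closer than 3 linewidths; spectral peaks may merge",
            stacklevel=2,
        )
    for omega0, conv, rng in zip(omegas, trap.convs, axis_rngs):
        if conv == 0.0:
            continue
        volts += conv * simulate_axis(
            omega0, trap.gamma0, trap.mass, trap.temperature,
            duration, sample_rate, rng,
        )
    if trap.noise_floor > 0:
        noise_rng = np.random.default_rng(noise_ss)
        sigma = math.sqrt(trap.noise_floor * sample_rate / 2.0)
        volts += sigma * noise_rng.standard_normal(n)
    metadata = {
        "pressure_mbar": trap.pressure / MBAR_TO_PA,
        "temperature_K": trap.temperature,
        "class_label": particle.class_label,
        "seed": seed,
        "overlapping_peaks": overlap_warning,
        "true_radius_m": particle.radius,
        "true_density_kg_m3": particle.density,
        "true_mass_kg": trap.mass,
        "true_gamma0_rad_s": trap.gamma0,
        "true_f_hz": tuple(w / (2.0 * math.pi) for w in omegas),
        "true_conv_V_m": trap.convs,
        "noise_floor_V2_Hz": trap.noise_floor,
    }
    return TimeTrace(sample_rate=sample_rate, samples=volts, metadata=metadata)


def generate_cohort(
    n_per_class: int,
    classes: list[ParticleSpec],
    radius_cv: float = 0.1,
    seed: int = 0,
    duration: float = 1.0,
    sample_rate: float = 1e6,
    pressure_mbar: float = DEFAULT_PRESSURE_MBAR,
    temperature: float = T_ENV,
    base_freqs: tuple[float, float, float] = DEFAULT_FREQS,
    conv: tuple[float, float, float] = DEFAULT_CONV,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
) -> list[TimeTrace]:
    """Generate a labelled cohort of detector traces.

    Each particle draws its radius from a normal distribution with the given
    coefficient of variation around its class template (the experiment's
    particle-size dispersion), then records one trace at the chamber
    pressure. Reproducible: the same seed yields bit-identical traces.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not classes:
        raise ValueError("classes must be a non-empty list of ParticleSpec")
    if not 0.0 <= radius_cv <= 0.5:
        raise ValueError("radius_cv must lie in [0, 0.5]")
    ss = np.random.SeedSequence(seed)
    traces: list[TimeTrace] = []
    for template, class_ss in zip(classes, ss.spawn(len(classes))):
        radius_rng = np.random.default_rng(class_ss)
        trace_seeds = class_ss.spawn(n_per_class)
        for k in range(n_per_class):
            radius = template.radius
            if radius_cv > 0:
                radius *= max(1.0 + radius_cv * radius_rng.standard_normal(), 0.1)
            spec = replace(template, radius=radius)
            trap = TrapParams.from_particle(
                spec, pressure_mbar, temperature, base_freqs, conv, noise_floor
            )
            trace_seed = int(trace_seeds[k].generate_state(1)[0] % (2**31))
            traces.append(
                synthesize_trace(spec, trap, duration, sample_rate, trace_seed)
            )
    return traces


def _offsets_for(
    molecule: shiftmodel.Molecule,
    coverage: float,
    base_freqs: tuple[float, float, float],
    radius: float,
) -> tuple[float, float, float]:
    s = shiftmodel.fractional_alpha_m_shift(
        molecule, shiftmodel.CoatedSphere(core_radius=radius), coverage
    )
    return tuple(f * s for f in base_freqs)


def default_class_specs(
    radius: float = DEFAULT_RADIUS,
    base_freqs: tuple[float, float, float] = DEFAULT_FREQS,
) -> list[ParticleSpec]:
    """Templates for the three-class experiment: standard, 25A, 25T.

    The functionalized classes carry trap-frequency offsets derived from the
    coated-sphere alpha/m model at full monolayer coverage, so the class
    effect in the synthetic data is the physical mechanism, not an arbitrary
    dial.
    """
    return [
        ParticleSpec(radius=radius, class_label="standard"),
        ParticleSpec(
            radius=radius,
            class_label="25A_1000uM",
            freq_offsets=_offsets_for(shiftmodel.ADENINE, 1.0, base_freqs, radius),
        ),
        ParticleSpec(
            radius=radius,
            class_label="25T_1000uM",
            freq_offsets=_offsets_for(shiftmodel.THYMINE, 1.0, base_freqs, radius),
        ),
    ]


#: Fraction of a full monolayer bound at each ZnCl2 concentration. Binding
#: increases with concentration; 500 and 750 uM are nearly equivalent,
#: reflecting the observed similarity of those two groups.
CONCENTRATION_COVERAGE = {100: 0.35, 500: 0.62, 750: 0.65, 1000: 1.0}


def concentration_series_specs(
    radius: float = DEFAULT_RADIUS,
    base_freqs: tuple[float, float, float] = DEFAULT_FREQS,
    coverages: dict[int, float] | None = None,
) -> list[ParticleSpec]:
    """Templates for the 25T ZnCl2-concentration experiment (4 classes)."""
    coverages = coverages or CONCENTRATION_COVERAGE
    return [
        ParticleSpec(
            radius=radius,
            class_label=f"25T_{conc}uM",
            freq_offsets=_offsets_for(
                shiftmodel.THYMINE, cov, base_freqs, radius
            ),
        )
        for conc, cov in sorted(coverages.items())
    ]


# --------------------------------------------------------------------------
# Trace I/O

def save_trace_hdf5(trace: TimeTrace, path) -> None:
    """Write a trace to HDF5: dataset ``samples``, metadata as attributes."""
    import h5py

    with h5py.File(path, "w") as h5:
        dset = h5.create_dataset("samples", data=trace.samples)
        dset.attrs["sample_rate"] = trace.sample_rate
        for key, value in trace.metadata.items():
            dset.attrs[key] = value


def load_trace_hdf5(path) -> TimeTrace:
    import h5py

    with h5py.File(path, "r") as h5:
        dset = h5["samples"]
        samples = dset[:]
        attrs = dict(dset.attrs)
    sample_rate = float(attrs.pop("sample_rate"))
    metadata = {
        k: (tuple(v) if isinstance(v, np.ndarray) else
            v.item() if isinstance(v, np.generic) else v)
        for k, v in attrs.items()
    }
    return TimeTrace(sample_rate=sample_rate, samples=samples, metadata=metadata)


def save_trace_csv(trace: TimeTrace, path) -> None:
    """Two-column CSV (time_s, voltage_V) for small fixtures."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "voltage_V"])
        for t, v in zip(trace.times, trace.samples):
            writer.writerow([repr(t), repr(v)])


def write_manifest(traces: list[TimeTrace], paths: list, manifest_path) -> None:
    """One row per trace: path, class, seed, true radius, true frequencies."""
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["path", "class_label", "seed", "true_radius_m",
             "true_f1_hz", "true_f2_hz", "true_f3_hz"]
        )
        for trace, path in zip(traces, paths):
            md = trace.metadata
            f1, f2, f3 = md.get("true_f_hz", (np.nan,) * 3)
            writer.writerow(
                [str(path), md.get("class_label", ""), md.get("seed", ""),
                 md.get("true_radius_m", ""), f1, f2, f3]
            )
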