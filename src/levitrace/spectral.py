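"""PSD estimation, Lorentzian peak fitting and calibration.

Implements the fitting stage of the analysis: Welch PSD estimation of the
detector trace, detection of the three motional peaks f1 < f2 < f3,
weighted nonlinear least-squares fits of the thermal-oscillator Lorentzian

    S(omega) = A / ((B^2 - omega^2)^2 + omega^2 C^2) + floor,

with A = gamma^2 kB T0 Gamma0 / (pi m), B = omega0 and C = Gamma0 as free
parameters, and the derived quantities:

* radius from the fitted damping C through the free-molecular gas-drag
  relation  r = 0.619 (9 pi / sqrt 2) (eta_air d^2 / (rho kB T0)) P / C,
* mass m = (4/3) pi r^3 rho,
* detector conversion factor gamma = sqrt(A pi m / (C kB T0)).

Spectra are stored one-sided in Hz (V^2/Hz, as recorded); the model and its
integrals live in angular frequency with two-sided normalisation. The
conversion between the two conventions is a factor 4*pi on the density and
2*pi on the abscissa, applied only in :func:`model_psd_hz` and
:func:`fit_lorentzian` (one documented place each way).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from .constants import D_AIR, ETA_AIR, KB, RHO_SILICA, T_ENV
from .simulate import TimeTrace

__all__ = [
    "PsdEstimate",
    "PeakFit",
    "DerivedParams",
    "FitReport",
    "PeakDetectionError",
    "FitError",
    "estimate_psd",
    "model_psd",
    "model_psd_hz",
    "find_peaks",
    "fit_lorentzian",
    "conversion_factor",
    "radius_from_damping",
    "particle_mass",
    "analyze_trace",
    "plot_peak_comparison",
]

PEAK_LABELS = ("f1", "f2", "f3")


class PeakDetectionError(RuntimeError):
    """Raised when fewer than the requested number of peaks is found."""

    def __init__(self, message: str, found: list[float]):
        super().__init__(message)
        self.found = found


class FitError(RuntimeError):
    """Raised when a Lorentzian fit fails; carries the diagnostics."""

    def __init__(self, message: str, p0, residuals=None):
        super().__init__(message)
        self.p0 = p0
        self.residuals = residuals


@dataclass
class PsdEstimate:
    """One-sided Welch PSD of a detector trace (V^2/Hz vs Hz)."""

    frequency: np.ndarray
    power: np.ndarray
    segment_length: int
    overlap: float
    window_name: str
    pressure: float = float("nan")   # Pa
    temperature: float = T_ENV

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequency.shape != self.power.shape:
            raise ValueError("frequency and power must have equal length")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def df(self) -> float:
        return float(self.frequency[1] - self.frequency[0])

    def to_csv(self, path) -> None:
        data = np.column_stack([self.frequency, self.power])
        np.savetxt(
            path, data, delimiter=",",
            header="frequency_Hz,power_V2_per_Hz", comments="",
        )


@dataclass
class PeakFit:
    """Fitted Lorentzian parameters for one motional peak.

    ``A`` (V^2 (rad/s)^3 scale), ``B`` = omega0 (rad/s), ``C`` = Gamma0
    (rad/s); ``noise_floor`` is the fitted additive floor in the same
    two-sided angular-frequency units as the model.
    """

    label: str
    A: float
    B: float
    C: float
    noise_floor: float
    covariance: np.ndarray
    window: tuple[float, float]    # Hz
    rss: float
    converged: bool

    @property
    def frequency_hz(self) -> float:
        return self.B / (2.0 * math.pi)

    @property
    def width_hz(self) -> float:
        return self.C / (2.0 * math.pi)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "A": self.A,
            "B_rad_s": self.B,
            "C_rad_s": self.C,
            "frequency_hz": self.frequency_hz,
            "width_hz": self.width_hz,
            "noise_floor": self.noise_floor,
            "sigma": np.sqrt(np.diag(self.covariance)).tolist(),
            "window_hz": list(self.window),
            "rss": self.rss,
            "converged": self.converged,
        }


@dataclass
class DerivedParams:
    """Calibration quantities derived from the peak fits."""

    conv_factor: float        # gamma, V/m
    radius: float             # m
    mass: float               # kg
    radius_per_peak: dict = field(default_factory=dict)
    source_peak: str = "f1"
    kinetic_regime: bool = True

    def to_dict(self) -> dict:
        return {
            "conv_factor_V_m": self.conv_factor,
            "radius_m": self.radius,
            "mass_kg": self.mass,
            "radius_per_peak_m": self.radius_per_peak,
            "source_peak": self.source_peak,
            "kinetic_regime": self.kinetic_regime,
        }


@dataclass
class FitReport:
    """Everything the fitting stage knows about one particle."""

    peaks: dict            # label -> PeakFit
    derived: DerivedParams | None
    metadata: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return (
            self.derived is not None
            and len(self.peaks) == len(PEAK_LABELS)
            and all(p.converged for p in self.peaks.values())
        )

    def to_json(self, path) -> None:
        payload = {
            "peaks": {k: v.to_dict() for k, v in self.peaks.items()},
            "derived": self.derived.to_dict() if self.derived else None,
            "metadata": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.metadata.items()
            },
            "settings": self.settings,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def estimate_psd(
    trace: TimeTrace,
    segment_length: int = 2**15,
    overlap: float = 0.5,
    window_name: str = "hann",
) -> PsdEstimate:
    """Welch-averaged one-sided PSD of a trace, in V^2/Hz."""
    n = trace.samples.size
    if segment_length > n:
        raise ValueError(
            f"segment_length {segment_length} exceeds trace length {n}"
        )
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    freq, power = signal.welch(
        trace.samples,
        fs=trace.sample_rate,
        window=window_name,
        nperseg=segment_length,
        noverlap=int(overlap * segment_length),
    )
    return PsdEstimate(
        frequency=freq,
        power=power,
        segment_length=segment_length,
        overlap=overlap,
        window_name=window_name,
        pressure=trace.metadata.get("pressure_mbar", float("nan")) * 100.0,
        temperature=trace.metadata.get("temperature_K", T_ENV),
    )


def model_psd(omega, A: float, B: float, C: float):
    """Thermal-oscillator Lorentzian A / ((B^2-w^2)^2 + w^2 C^2).

    Two-sided density over angular frequency: its integral over all omega is
    pi*A/(B^2*C), the equipartition variance when A carries its physical
    definition.
    """
    omega = np.asarray(omega, dtype=float)
    return A / ((B**2 - omega**2) ** 2 + omega**2 * C**2)


def model_psd_hz(freq, A: float, B: float, C: float, noise_floor: float = 0.0):
    """One-sided PSD in V^2/Hz at frequency in Hz for the same parameters."""
    return 4.0 * math.pi * (model_psd(2.0 * math.pi * np.asarray(freq), A, B, C)
                            + noise_floor)


def find_peaks(
    psd: PsdEstimate,
    n_peaks: int = 3,
    min_separation: float = 10e3,
    min_frequency: float = 5e3,
) -> list[tuple[float, float, str]]:
    """Locate the motional peaks and return fit windows.

    Returns ``n_peaks`` windows ``(f_lo, f_hi, label)`` ordered and labelled
    by ascending frequency. Each window extends several estimated linewidths
    around its peak but never past the midpoint to a neighbouring peak.
    Raises :class:`PeakDetectionError` when fewer prominences are found;
    warns when two peaks are closer than ``min_separation``.
    """
    from scipy.ndimage import uniform_filter1d

    mask = psd.frequency >= min_frequency
    freq = psd.frequency[mask]
    power = psd.power[mask]
    if freq.size < 10:
        raise PeakDetectionError("PSD covers too little bandwidth", [])
    # smooth before locating extents: single Welch bins scatter by ~100%
    power = uniform_filter1d(power, size=7, mode="nearest")
    logp = np.log10(np.maximum(power, np.finfo(float).tiny))
    # prominence on the log scale: thermal peaks stand decades above floor
    idx, props = signal.find_peaks(logp, prominence=1.0)
    if idx.size < n_peaks:
        idx, props = signal.find_peaks(logp, prominence=0.3)
    if idx.size < n_peaks:
        raise PeakDetectionError(
            f"found {idx.size} peak(s), expected {n_peaks}",
            found=freq[idx].tolist(),
        )
    order = np.argsort(props["prominences"])[::-1][:n_peaks]
    sel = np.sort(idx[order])
    centres = freq[sel]
    if np.any(np.diff(centres) < min_separation):
        warnings.warn(
            "detected peaks closer than min_separation; windows were merged "
            "at their midpoint",
            stacklevel=2,
        )
    windows = []
    for rank, i in enumerate(sel):
        # local FWHM estimate for the window half-width; the window should
        # span several linewidths so the fit sees the Lorentzian wings
        half = power[i] / 2.0
        lo = i
        while lo > 0 and power[lo] > half:
            lo -= 1
        hi = i
        while hi < power.size - 1 and power[hi] > half:
            hi += 1
        fwhm = max(freq[hi] - freq[lo], 10 * psd.df)
        half_width = max(3.0 * fwhm, 30 * psd.df)
        f_lo = max(freq[i] - half_width, min_frequency)
        f_hi = min(freq[i] + half_width, freq[-1])
        if rank > 0:
            f_lo = max(f_lo, 0.5 * (centres[rank - 1] + centres[rank]))
        if rank < n_peaks - 1:
            f_hi = min(f_hi, 0.5 * (centres[rank] + centres[rank + 1]))
        windows.append((f_lo, f_hi, PEAK_LABELS[rank] if n_peaks == 3 else f"f{rank+1}"))
    return windows


def fit_lorentzian(
    psd: PsdEstimate,
    window: tuple[float, float],
    label: str = "f1",
) -> PeakFit:
    """Weighted least-squares Lorentzian fit inside one frequency window.

    The data are converted to two-sided angular-frequency units, fitted with
    the model plus an additive noise-floor nuisance parameter, first with
    weights from the data then reweighted by the fitted model
    (Welch-estimate errors scale with the local mean). Initialisation is
    deterministic: B from the peak bin, C from the half-maximum width, A
    from the on-resonance height.
    """
    f_lo, f_hi = window[0], window[1]
    mask = (psd.frequency >= f_lo) & (psd.frequency <= f_hi)
    if int(mask.sum()) < 10:
        raise ValueError("window must contain at least 10 frequency bins")
    omega = 2.0 * math.pi * psd.frequency[mask]
    pow_omega = psd.power[mask] / (4.0 * math.pi)

    i_pk = int(np.argmax(pow_omega))
    b0 = omega[i_pk]
    above = omega[pow_omega > pow_omega[i_pk] / 2.0]
    c0 = max(float(np.ptp(above)) if above.size else 0.0, omega[1] - omega[0])
    floor0 = float(np.median(pow_omega))
    a0 = max((pow_omega[i_pk] - floor0) * b0**2 * c0**2, pow_omega[i_pk] * 1e-3)
    p0 = [a0, b0, c0, floor0]

    def mdl(om, A, B, C, D):
        return model_psd(om, A, B, C) + D

    bounds = ([0.0, omega[0], 0.0, 0.0],
              [np.inf, omega[-1], np.inf, np.inf])
    try:
        popt, pcov = curve_fit(
            mdl, omega, pow_omega, p0=p0, sigma=np.maximum(pow_omega, a0 * 1e-30),
            bounds=bounds, maxfev=20000,
        )
        popt, pcov = curve_fit(
            mdl, omega, pow_omega, p0=popt, sigma=mdl(omega, *popt),
            bounds=bounds, maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(
            f"Lorentzian fit did not converge in window "
            f"({f_lo:g}, {f_hi:g}) Hz: {exc}",
            p0=p0,
            residuals=pow_omega - mdl(omega, *p0),
        ) from exc
    a, b, c, d = popt
    resid = pow_omega - mdl(omega, *popt)
    window_width_omega = omega[-1] - omega[0]
    converged = bool(
        a > 0 and c > 0
        and omega[0] <= b <= omega[-1]
        and c < window_width_omega
    )
    return PeakFit(
        label=label, A=float(a), B=float(b), C=float(c), noise_floor=float(d),
        covariance=pcov[:3, :3], window=(f_lo, f_hi),
        rss=float(np.sum(resid**2)), converged=converged,
    )


def conversion_factor(fit: PeakFit, mass: float, temperature: float = T_ENV) -> float:
    """Detector conversion factor gamma (V/m) from a fitted peak.

    Inverts the amplitude definition A = gamma^2 kB T0 Gamma0 / (pi m):
    gamma = sqrt(A pi m / (C kB T0)).
    """
    if mass <= 0 or temperature <= 0:
        raise ValueError("mass and temperature must be positive")
    if fit.A <= 0 or fit.C <= 0:
        raise ValueError("fit parameters must be positive")
    return math.sqrt(fit.A * math.pi * mass / (fit.C * KB * temperature))


def radius_from_damping(
    fit: PeakFit | float,
    pressure: float,
    temperature: float = T_ENV,
    density: float = RHO_SILICA,
    eta_air: float = ETA_AIR,
    d_air: float = D_AIR,
) -> tuple[float, bool]:
    """Particle radius (m) from the fitted damping rate C = Gamma0.

    Free-molecular gas-drag inversion
    ``r = 0.619 (9 pi / sqrt 2) eta d^2 / (rho kB T0) * P / C``; ``pressure``
    in Pa. Returns ``(radius, kinetic_regime)`` where the flag is False when
    the Knudsen number (mean free path / radius) drops below 10 and the
    free-molecular formula loses validity.
    """
    c = fit.C if isinstance(fit, PeakFit) else float(fit)
    if c <= 0 or pressure <= 0:
        raise ValueError("damping rate and pressure must be positive")
    radius = (
        0.619 * 9.0 * math.pi / math.sqrt(2.0)
        * eta_air * d_air**2 / (density * KB * temperature)
        * pressure / c
    )
    mean_free_path = KB * temperature / (
        math.sqrt(2.0) * math.pi * d_air**2 * pressure
    )
    return radius, bool(mean_free_path / radius >= 10.0)


def particle_mass(radius: float, density: float = RHO_SILICA) -> float:
    """Spherical-particle mass (4/3) pi r^3 rho (kg)."""
    if radius < 0 or density <= 0:
        raise ValueError("radius must be >= 0, density > 0")
    return 4.0 / 3.0 * math.pi * radius**3 * density


def analyze_trace(
    trace: TimeTrace,
    segment_length: int = 2**15,
    overlap: float = 0.5,
    window_name: str = "hann",
    density: float = RHO_SILICA,
    source_peak: str = "f1",
    min_separation: float = 10e3,
    min_frequency: float = 5e3,
) -> FitReport:
    """Full fitting stage for one trace: PSD -> peaks -> fits -> calibration.

    The pipeline order is acyclic: the radius comes from the damping of the
    chosen source peak (f1, the z axis, by default), the mass from the
    radius, and the conversion factor gamma from the source peak's amplitude
    with that mass. A radius is recorded for every peak (one gas, one
    particle: each peak's width estimates the same radius).
    """
    psd = estimate_psd(trace, segment_length, overlap, window_name)
    settings = {
        "segment_length": segment_length,
        "overlap": overlap,
        "window_name": window_name,
        "density_kg_m3": density,
        "source_peak": source_peak,
    }
    peaks: dict[str, PeakFit] = {}
    try:
        windows = find_peaks(psd, 3, min_separation, min_frequency)
        for f_lo, f_hi, label in windows:
            peaks[label] = fit_lorentzian(psd, (f_lo, f_hi), label)
    except (PeakDetectionError, FitError, ValueError) as exc:
        return FitReport(
            peaks=peaks, derived=None,
            metadata={**trace.metadata, "failure": str(exc)},
            settings=settings,
        )
    pressure = psd.pressure
    radius_per_peak = {}
    kinetic = True
    for label, pk in peaks.items():
        r, flag = radius_from_damping(
            pk, pressure, psd.temperature, density
        )
        radius_per_peak[label] = r
        kinetic = kinetic and flag
    radius = radius_per_peak[source_peak]
    mass = particle_mass(radius, density)
    gamma = conversion_factor(peaks[source_peak], mass, psd.temperature)
    derived = DerivedParams(
        conv_factor=gamma, radius=radius, mass=mass,
        radius_per_peak=radius_per_peak, source_peak=source_peak,
        kinetic_regime=kinetic,
    )
    return FitReport(
        peaks=peaks, derived=derived, metadata=dict(trace.metadata),
        settings=settings,
    )


def plot_peak_comparison(
    psds_by_label: dict[str, PsdEstimate],
    windows: list[tuple[float, float]],
    path,
) -> None:
    """Three-panel overlay of the f1/f2/f3 peaks across particle classes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(windows), figsize=(4 * len(windows), 3.2))
    axes = np.atleast_1d(axes)
    for ax, (f_lo, f_hi), label in zip(axes, windows, PEAK_LABELS):
        for cls, psd in psds_by_label.items():
            m = (psd.frequency >= f_lo) & (psd.frequency <= f_hi)
            ax.semilogy(psd.frequency[m] / 1e3, psd.power[m], label=cls, lw=0.8)
        ax.set_xlabel("frequency (kHz)")
        ax.set_title(label)
    axes[0].set_ylabel(r"PSD (V$^2$/Hz)")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
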