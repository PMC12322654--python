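"""Nuclear-ensemble UV-vis spectra from vertical excitations.

A spectrum is assembled by Gaussian-broadening the vertical excitation
energies of many thermally sampled geometries, each line weighted by its
oscillator strength:

    I(E) = (1/N) * sum_i f_i * G(E - E_i; fwhm)

with G a unit-area Gaussian.  The integral of I over energy therefore equals
the mean oscillator strength (the absolute cross-section prefactor is left as
a documented constant of 1).  Computed spectra carry a systematic error in
the excitation energies, which is removed by calibrating a scalar energy
shift (plus an amplitude scale, since computed intensities are relative)
against an experimental spectrum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import HC_EV_NM

__all__ = [
    "ExcitationRecord",
    "EnsembleSpectrum",
    "ExperimentalSpectrum",
    "WavelengthTrace",
    "BandMetrics",
    "read_excitation_table",
    "assemble_spectrum",
    "to_wavelength",
    "calibrate_shift",
    "band_metrics",
    "cis_trans_split",
    "epsilon_from_absorbance",
    "absorbance_from_epsilon",
    "DEFAULT_FWHM_EV",
    "DEFAULT_GRID",
    "NPI_BAND_WINDOW_NM",
]

#: default Gaussian broadening FWHM in eV
DEFAULT_FWHM_EV = 0.15
#: default energy grid: (start eV, stop eV, step eV)
DEFAULT_GRID = (1.5, 4.5, 0.002)
#: default wavelength window bracketing the visible n->pi* band
NPI_BAND_WINDOW_NM = (380.0, 780.0)


@dataclass(frozen=True)
class ExcitationRecord:
    """One snapshot's vertical excitation."""

    frame_index: int
    isomer: str  # "cis" or "trans"
    energy: float  # eV
    strength: float  # oscillator strength, dimensionless
    features: dict | None = None

    def __post_init__(self) -> None:
        if not (self.energy > 0):
            raise ValueError(f"excitation energy must be positive, got {self.energy}")
        if self.strength < 0:
            raise ValueError(f"oscillator strength must be >= 0, got {self.strength}")
        if self.isomer not in ("cis", "trans"):
            raise ValueError(f"isomer must be 'cis' or 'trans', got {self.isomer!r}")


@dataclass
class EnsembleSpectrum:
    """Broadened spectrum on a uniform energy grid (eV)."""

    energy_ev: np.ndarray
    intensity: np.ndarray
    n_records: int
    broadening_fwhm: float
    shift: float = 0.0

    def __post_init__(self) -> None:
        self.energy_ev = np.asarray(self.energy_ev, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.energy_ev) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(self.intensity < -1e-300):
            raise ValueError("intensity must be non-negative")

    def shifted(self, delta_ev: float) -> "EnsembleSpectrum":
        """Spectrum with all transition energies moved by ``delta_ev``.

        Implemented by shifting the grid labels, so no re-broadening error."""
        return EnsembleSpectrum(
            self.energy_ev + delta_ev,
            self.intensity.copy(),
            self.n_records,
            self.broadening_fwhm,
            shift=self.shift + delta_ev,
        )

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.energy_ev))


@dataclass
class WavelengthTrace:
    """A spectrum on an ascending wavelength grid (nm)."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")


@dataclass
class ExperimentalSpectrum:
    """Measured wavelength/absorbance trace with Beer-Lambert metadata."""

    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    concentration: float | None = None  # mol/L
    path_length: float = 1.0  # cm

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")


@dataclass(frozen=True)
class BandMetrics:
    lambda_max: float  # nm
    intensity_max: float
    tail_extent: float  # nm, longest wavelength above threshold
    threshold_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.tail_extent < self.lambda_max - 1e-9:
            raise ValueError("tail extent cannot lie blueward of the band maximum")


def read_excitation_table(path: str | Path) -> pd.DataFrame:
    """Read an excitation CSV with columns frame,isomer,energy_eV,osc_strength
    plus any extra feature columns."""
    df = pd.read_csv(path)
    required = {"frame", "isomer", "energy_eV", "osc_strength"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"excitation table missing columns {sorted(missing)}")
    return df


def _records_to_arrays(
    records: Sequence[ExcitationRecord] | pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        return records["energy_eV"].to_numpy(float), records["osc_strength"].to_numpy(float)
    return (
        np.array([r.energy for r in records], dtype=float),
        np.array([r.strength for r in records], dtype=float),
    )


def assemble_spectrum(
    records: Sequence[ExcitationRecord] | pd.DataFrame,
    fwhm: float = DEFAULT_FWHM_EV,
    grid: tuple[float, float, float] = DEFAULT_GRID,
) -> EnsembleSpectrum:
    """Broaden an ensemble of lines into a spectrum on a uniform energy grid."""
    energies, strengths = _records_to_arrays(records)
    if energies.size == 0:
        raise ValueError("cannot assemble a spectrum from zero excitation records")
    if not fwhm > 0:
        raise ValueError(f"broadening FWHM must be positive, got {fwhm}")
    start, stop, step = grid
    e = np.arange(start, stop + step / 2, step)

    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    inside = (energies >= e[0] + 5 * sigma) & (energies <= e[-1] - 5 * sigma)
    if not np.all(inside):
        warnings.warn(
            f"{int(np.sum(~inside))} lines lie within 5 sigma of (or outside) the grid "
            "edges; their tails are truncated",
            RuntimeWarning,
            stacklevel=2,
        )
    # unit-area Gaussian per line, weighted by f, averaged over records
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    diff = (e[None, :] - energies[:, None]) / sigma
    intensity = (strengths[:, None] * np.exp(-0.5 * diff**2)).sum(axis=0)
    intensity *= norm / energies.size
    return EnsembleSpectrum(e, intensity, int(energies.size), fwhm)


def to_wavelength(spec: EnsembleSpectrum, jacobian: bool = False) -> WavelengthTrace:
    """Convert an energy-domain spectrum to wavelength (nm).

    With ``jacobian=False`` (default, matching common ensemble-spectrum
    plotting practice) the intensity values are carried over unchanged; with
    ``jacobian=True`` the density transform |dE/dlambda| = E^2/hc is applied.
    """
    lam = HC_EV_NM / spec.energy_ev
    intens = spec.intensity.copy()
    if jacobian:
        intens = intens * spec.energy_ev**2 / HC_EV_NM
    order = np.argsort(lam)
    return WavelengthTrace(lam[order], intens[order])


def _interp_window(
    trace_lam: np.ndarray,
    trace_int: np.ndarray,
    target_lam: np.ndarray,
) -> np.ndarray:
    return np.interp(target_lam, trace_lam, trace_int, left=0.0, right=0.0)


def calibrate_shift(
    computed: EnsembleSpectrum,
    experimental: ExperimentalSpectrum,
    window: tuple[float, float] = NPI_BAND_WINDOW_NM,
    search_ev: float = 0.5,
    step_ev: float = 0.001,
    normalize: bool = True,
) -> tuple[float, float, EnsembleSpectrum]:
    """Find the scalar energy shift aligning a computed spectrum to experiment.

    Minimizes the least-squares difference between the (shifted, scaled)
    computed trace and the experimental trace on the experimental wavelength
    grid restricted to ``window``.  The amplitude scale is solved in closed
    form at each candidate shift; the shift is scanned on a ``step_ev`` grid
    over +/- ``search_ev`` and refined by a 3-point parabola.

    Returns ``(shift_eV, scale, shifted_spectrum)``.  A positive shift means
    the computed transition energies had to be raised (spectrum moved to the
    blue) to match.
    """
    lo, hi = window
    mask = (experimental.wavelength_nm >= lo) & (experimental.wavelength_nm <= hi)
    if not np.any(mask):
        raise ValueError(f"window {window} nm does not overlap the experimental grid")
    lam_exp = experimental.wavelength_nm[mask]
    y_exp = experimental.absorbance[mask].astype(float)
    if normalize:
        peak = float(np.max(np.abs(y_exp)))
        if peak == 0:
            raise ValueError("experimental trace is identically zero in the window")
        y_exp = y_exp / peak

    comp_lam_window = HC_EV_NM / np.array([computed.energy_ev[-1], computed.energy_ev[0]])
    if comp_lam_window[0] > hi or comp_lam_window[1] < lo:
        raise ValueError("window does not overlap the computed spectrum")

    base_int = computed.intensity
    if normalize:
        cpk = float(np.max(base_int))
        if cpk == 0:
            raise ValueError("computed spectrum is identically zero")
        base_int = base_int / cpk

    def sse_and_scale(shift: float) -> tuple[float, float]:
        lam = HC_EV_NM / (computed.energy_ev + shift)
        order = np.argsort(lam)
        y_c = _interp_window(lam[order], base_int[order], lam_exp)
        denom = float(np.dot(y_c, y_c))
        if denom == 0:
            return float(np.dot(y_exp, y_exp)), 0.0
        scale = float(np.dot(y_c, y_exp)) / denom
        resid = y_exp - scale * y_c
        return float(np.dot(resid, resid)), scale

    shifts = np.arange(-search_ev, search_ev + step_ev / 2, step_ev)
    sses = np.array([sse_and_scale(s)[0] for s in shifts])
    i = int(np.argmin(sses))
    best = shifts[i]
    if 0 < i < len(shifts) - 1:  # parabolic refinement
        y0, y1, y2 = sses[i - 1], sses[i], sses[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            best = shifts[i] + 0.5 * step_ev * (y0 - y2) / denom
    _, scale = sse_and_scale(best)
    if normalize:
        scale *= peak / cpk
    return float(best), float(scale), computed.shifted(float(best))


def band_metrics(
    trace: WavelengthTrace | ExperimentalSpectrum,
    window: tuple[float, float] = NPI_BAND_WINDOW_NM,
    threshold_fraction: float = 0.01,
) -> BandMetrics:
    """Band maximum (with 3-point parabolic refinement) and tail extent.

    The tail extent is the longest wavelength inside ``window`` at which the
    intensity is still at or above ``threshold_fraction`` of the band peak
    (linear interpolation between grid points); it marks where absorption
    nears zero and photoswitching stops being productive.
    """
    lam = trace.wavelength_nm
    y = trace.intensity if isinstance(trace, WavelengthTrace) else trace.absorbance
    mask = (lam >= window[0]) & (lam <= window[1])
    if np.sum(mask) < 3:
        raise ValueError(f"window {window} nm contains fewer than 3 points")
    lam = lam[mask]
    y = np.asarray(y, dtype=float)[mask]
    peak_val = float(np.max(y))
    if peak_val <= 0 or np.ptp(y) == 0:
        raise ValueError("trace is flat or non-positive in the window; no band to measure")

    i = int(np.argmax(y))
    lam_max, y_max = lam[i], peak_val
    if 0 < i < len(lam) - 1:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            frac = 0.5 * (y0 - y2) / denom
            lam_max = lam[i] + frac * (lam[i + 1] - lam[i - 1]) / 2.0
            y_max = y1 - 0.25 * (y0 - y2) * frac

    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    thr = threshold_fraction * y_max
    above = np.flatnonzero(y >= thr)
    j = int(above[-1])
    tail = lam[j]
    if j < len(lam) - 1 and y[j + 1] < thr:  # interpolate the crossing
        tail = lam[j] + (lam[j + 1] - lam[j]) * (y[j] - thr) / (y[j] - y[j + 1])
    tail = max(tail, lam_max)
    return BandMetrics(float(lam_max), float(y_max), float(tail), threshold_fraction)


def cis_trans_split(metrics_cis: BandMetrics, metrics_trans: BandMetrics) -> float:
    """Band-maximum separation lambda_max(trans) - lambda_max(cis), in nm.

    Positive when the trans band lies to the red of the cis band, as for
    ortho-substituted azobenzenes (~50 nm for the n->pi* band)."""
    return metrics_trans.lambda_max - metrics_cis.lambda_max


def epsilon_from_absorbance(spec: ExperimentalSpectrum) -> np.ndarray:
    """Molar absorptivity trace eps(lambda) = A / (c*l), L/(mol*cm)."""
    if spec.concentration is None or not spec.concentration > 0:
        raise ValueError("concentration metadata required to compute molar absorptivity")
    if not spec.path_length > 0:
        raise ValueError("path length must be positive")
    return spec.absorbance / (spec.concentration * spec.path_length)


def absorbance_from_epsilon(
    wavelength_nm: np.ndarray,
    epsilon: np.ndarray,
    concentration: float,
    path_length: float = 1.0,
) -> ExperimentalSpectrum:
    """Inverse of :func:`epsilon_from_absorbance` (Beer-Lambert)."""
    return ExperimentalSpectrum(
        np.asarray(wavelength_nm, float),
        np.asarray(epsilon, float) * concentration * path_length,
        concentration=concentration,
        path_length=path_length,
    )
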