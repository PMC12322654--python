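"""Two-state photoswitching and relaxation kinetics.

The isomer populations under irradiation follow

    dx_c/dt = (I0/C) * (1 - 10**(-A)) * (f_t*Phi_tc - f_c*Phi_ct) - k_th*x_c

where x_c is the cis fraction, I0 the volumetric photon flux
(einstein L^-1 s^-1), A the absorbance at the irradiation wavelength,
f_i = eps_i*c_i*l/A the fraction of absorbed photons captured by isomer i,
Phi the isomerization quantum yields and k_th the thermal cis->trans rate.
In the dark the cis fraction simply relaxes exponentially.

The quantum-yield estimator reconstructs Phi_tc from an absorbance time
course at an analysis wavelength, anchored by NMR-derived trans:cis ratios:
the absorbance is mapped linearly onto the cis fraction through the anchors,
the initial conversion rate is taken from a linear fit restricted to early
times, and Phi_tc is the initial molar conversion rate divided by the photon
rate absorbed by the trans isomer.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .constants import LN2
from .thermokinetics import BarrierEstimate, HalfLife, Temperature, barrier_from_halflife

logger = logging.getLogger(__name__)

__all__ = [
    "IsomerRatio",
    "PhotokineticModel",
    "KineticTrace",
    "DecayModel",
    "DecayFit",
    "QuantumYieldEstimate",
    "simulate_photoswitching",
    "pss_closed_form",
    "estimate_quantum_yield",
    "fit_mono_decay",
    "fit_bi_decay",
    "fit_decay",
    "halflife_report",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class IsomerRatio:
    """trans/cis populations as fractions summing to 1."""

    trans_fraction: float
    cis_fraction: float

    def __post_init__(self) -> None:
        for name, v in (("trans", self.trans_fraction), ("cis", self.cis_fraction)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} fraction must be in [0, 1], got {v}")
        if abs(self.trans_fraction + self.cis_fraction - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 within 1e-9")

    @classmethod
    def from_cis(cls, cis_fraction: float) -> "IsomerRatio":
        return cls(1.0 - cis_fraction, cis_fraction)

    @classmethod
    def from_ratio(cls, trans: float, cis: float) -> "IsomerRatio":
        """From a trans:cis ratio such as (8, 92)."""
        total = trans + cis
        if total <= 0:
            raise ValueError("ratio parts must sum to a positive value")
        return cls(trans / total, cis / total)


@dataclass(frozen=True)
class PhotokineticModel:
    """Two-state isomerization parameters at one irradiation wavelength."""

    phi_tc: float  # quantum yield trans->cis
    phi_ct: float  # quantum yield cis->trans
    eps_t: float  # molar absorptivity of trans at the irradiation wavelength, L/(mol cm)
    eps_c: float
    photon_flux: float  # volumetric incident photon rate, einstein L^-1 s^-1
    path_length: float = 1.0  # cm
    k_thermal: float = 0.0  # thermal cis->trans rate, 1/s
    total_conc: float = 5e-4  # mol/L

    def __post_init__(self) -> None:
        for name in ("phi_tc", "phi_ct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a quantum yield in [0, 1], got {v}")
        for name in ("eps_t", "eps_c", "photon_flux", "k_thermal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("path_length", "total_conc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def absorbance_irr(self, x_c: float) -> float:
        """Absorbance at the irradiation wavelength for cis fraction x_c."""
        return (
            (self.eps_t * (1 - x_c) + self.eps_c * x_c) * self.total_conc * self.path_length
        )


@dataclass
class KineticTrace:
    """A time series of absorbance or cis fraction at a fixed temperature."""

    times: np.ndarray  # s, strictly increasing
    signal: np.ndarray
    temperature: Temperature | None = None
    signal_kind: str = "absorbance"  # or "cis_fraction"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.signal_kind not in ("absorbance", "cis_fraction"):
            raise ValueError(f"unknown signal kind {self.signal_kind!r}")


def _photo_rate(model: PhotokineticModel, x_c: float, optically_thin: bool) -> float:
    """d x_c/dt from the photochemical terms only."""
    et = model.eps_t * (1 - x_c)
    ec = model.eps_c * x_c
    denom = et + ec
    if denom <= 0:
        return 0.0
    a = denom * model.total_conc * model.path_length
    absorbed = a * LN10 if optically_thin else (1.0 - 10.0 ** (-a))
    f_t = et / denom
    f_c = ec / denom
    return (
        model.photon_flux
        * absorbed
        * (f_t * model.phi_tc - f_c * model.phi_ct)
        / model.total_conc
    )


def simulate_photoswitching(
    model: PhotokineticModel,
    schedule: Sequence[tuple[float, bool]],
    x0: IsomerRatio = IsomerRatio(1.0, 0.0),
    points_per_segment: int = 100,
    optically_thin: bool = False,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> KineticTrace:
    """Integrate the cis fraction through a light-on/light-off schedule.

    ``schedule`` is a list of (duration in s, light on?) segments.  Dark
    segments are propagated with the exact exponential; lit segments with an
    adaptive LSODA integration of the full (or optically thin) photon-balance
    ODE.  Returns a cis-fraction trace; trans is 1 - cis by construction.
    """
    if not schedule:
        raise ValueError("schedule must contain at least one segment")
    times = [0.0]
    values = [x0.cis_fraction]
    t0 = 0.0
    xc = x0.cis_fraction
    for duration, light_on in schedule:
        if duration <= 0:
            raise ValueError("segment durations must be positive")
        t_local = np.linspace(0.0, duration, points_per_segment + 1)[1:]
        if not light_on:
            xc_seg = xc * np.exp(-model.k_thermal * t_local)
        else:

            def rhs(t: float, y: np.ndarray) -> list[float]:
                return [_photo_rate(model, y[0], optically_thin) - model.k_thermal * y[0]]

            sol = solve_ivp(
                rhs,
                (0.0, duration),
                [xc],
                t_eval=t_local,
                method="LSODA",
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise RuntimeError(f"photoswitching integration failed: {sol.message}")
            xc_seg = np.clip(sol.y[0], 0.0, 1.0)
        times.extend(t0 + t_local)
        values.extend(xc_seg)
        xc = float(values[-1])
        t0 += duration
    return KineticTrace(
        np.array(times),
        np.array(values),
        signal_kind="cis_fraction",
        metadata={"model": model, "schedule": list(schedule)},
    )


def pss_closed_form(model: PhotokineticModel) -> IsomerRatio:
    """Photostationary cis:trans ratio under continuous irradiation.

    With no thermal relaxation the photon-absorption nonlinearity cancels and
    x_c = eps_t*Phi_tc / (eps_t*Phi_tc + eps_c*Phi_ct).  With thermal
    relaxation the steady state of the optically thin photon balance is
    x_c = a / (a + b + k_th), a = I0*ln10*l*eps_t*Phi_tc and
    b = I0*ln10*l*eps_c*Phi_ct.
    """
    a = model.eps_t * model.phi_tc
    b = model.eps_c * model.phi_ct
    if a == 0 and b == 0 and model.k_thermal == 0:
        raise ValueError("all photochemical and thermal rates are zero; no steady state")
    if model.k_thermal == 0:
        if a + b == 0:
            raise ValueError("no photochemical rate and no thermal relaxation")
        return IsomerRatio.from_cis(a / (a + b))
    ka = model.photon_flux * LN10 * model.path_length * a
    kb = model.photon_flux * LN10 * model.path_length * b
    return IsomerRatio.from_cis(ka / (ka + kb + model.k_thermal))


@dataclass(frozen=True)
class QuantumYieldEstimate:
    phi: float
    stderr: float
    n_points: int
    a_trans: float  # calibrated pure-trans absorbance at the analysis wavelength
    a_cis: float


def estimate_quantum_yield(
    trace: KineticTrace,
    anchors: Sequence[tuple[float, IsomerRatio]],
    photon_flux_einstein_per_s: float,
    volume_liters: float,
    absorbance_irr: float,
    total_conc: float,
    initial_trans_absorbed_fraction: float = 1.0,
    conversion_window: float = 0.10,
) -> QuantumYieldEstimate:
    """Initial-rate, NMR-anchored estimate of the trans->cis quantum yield.

    Parameters
    ----------
    trace:
        Absorbance at the analysis wavelength versus irradiation time.
    anchors:
        At least two (time, isomer ratio) pairs from NMR, spanning the
        conversion; they calibrate the linear absorbance -> cis-fraction map.
    photon_flux_einstein_per_s:
        Photon rate delivered to the sample, einstein/s.
    absorbance_irr:
        Absorbance of the (trans-rich) starting solution at the irradiation
        wavelength; sets the absorbed photon fraction 1 - 10**(-A).
    initial_trans_absorbed_fraction:
        Fraction of absorbed photons captured by the trans isomer at t -> 0
        (1.0 for a dark-adapted all-trans start).
    conversion_window:
        Only points within this much cis-fraction conversion beyond the start
        enter the initial-slope fit (default 10%).
    """
    if photon_flux_einstein_per_s <= 0:
        raise ValueError("photon flux must be positive; no photons, no conversion")
    if len(anchors) < 2:
        raise ValueError("need at least two NMR anchors to calibrate the absorbance scale")
    if absorbance_irr <= 0:
        raise ValueError("absorbance at the irradiation wavelength is required")

    t_anchor = np.array([t for t, _ in anchors], dtype=float)
    x_anchor = np.array([r.cis_fraction for _, r in anchors], dtype=float)
    if np.ptp(x_anchor) <= 0:
        raise ValueError("anchors do not span any conversion range")
    a_anchor = np.interp(t_anchor, trace.times, trace.signal)
    # A = A_t*(1-x) + A_c*x, solved in least squares over the anchors
    design = np.column_stack([1.0 - x_anchor, x_anchor])
    (a_t, a_c), *_ = np.linalg.lstsq(design, a_anchor, rcond=None)
    if abs(a_c - a_t) < 1e-12:
        raise ValueError("anchors give no absorbance contrast between isomers")

    x_c = (trace.signal - a_t) / (a_c - a_t)
    x0 = float(x_c[0])
    early = x_c - x0 <= conversion_window
    # keep the contiguous early stretch only
    cut = int(np.argmin(early)) if not early.all() else len(x_c)
    if cut < 3:
        raise ValueError("fewer than 3 points inside the initial conversion window")
    t_fit, x_fit = trace.times[:cut], x_c[:cut]

    # Initial-rate fit.  The conversion rate declines across the window
    # (trans depletion, falling absorbed-photon rate, back-reaction), so a
    # straight line through the window underestimates the t=0 slope by about
    # half the window; a quadratic in t absorbs that curvature and its linear
    # coefficient is the initial rate.  Fall back to a line when the window
    # holds too few points to support three parameters.
    degree = 2 if cut >= 10 else 1
    design = np.column_stack([t_fit**d for d in range(degree, -1, -1)])
    coef, residuals, *_ = np.linalg.lstsq(design, x_fit, rcond=None)
    slope = float(coef[-2])  # coefficient of t
    if slope <= 0:
        raise ValueError("non-positive initial conversion rate; check anchor ordering")
    dof = len(t_fit) - (degree + 1)
    if dof > 0 and len(residuals):
        s2 = float(residuals[0]) / dof
        cov = s2 * np.linalg.inv(design.T @ design)
        slope_err = math.sqrt(cov[-2, -2])
    else:
        slope_err = float("nan")

    n_total = total_conc * volume_liters  # mol of switch
    absorbed = (
        photon_flux_einstein_per_s
        * (1.0 - 10.0 ** (-absorbance_irr))
        * initial_trans_absorbed_fraction
    )  # einstein/s absorbed by trans at t -> 0
    phi = n_total * slope / absorbed
    stderr = n_total * slope_err / absorbed if math.isfinite(slope_err) else float("nan")
    return QuantumYieldEstimate(float(phi), float(stderr), cut, float(a_t), float(a_c))


class DecayModel(str, Enum):
    mono = "mono"
    bi = "bi"


@dataclass
class DecayFit:
    """Result of an exponential-decay fit."""

    model: DecayModel
    rates: tuple[float, ...]  # 1/s; for bi: (k_fast, k_slow)
    amplitudes: tuple[float, ...]
    offset: float
    covariance: np.ndarray | None
    sse: float
    n: int

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.rates):
            raise ValueError("fitted rates must be positive")
        if self.model is DecayModel.bi and len(self.rates) == 2:
            if self.rates[0] < self.rates[1]:
                raise ValueError("bi-exponential rates must be ordered fast, slow")

    @property
    def half_lives(self) -> tuple[HalfLife, ...]:
        return tuple(HalfLife(LN2 / k) for k in self.rates)

    @property
    def n_params(self) -> int:
        return 1 + 2 * len(self.rates)

    @property
    def aicc(self) -> float:
        """Corrected Akaike information criterion (Gaussian residuals)."""
        n, p = self.n, self.n_params
        if n <= p + 1:
            return float("inf")
        sse = max(self.sse, 1e-300)
        return n * math.log(sse / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.offset)
        for a, k in zip(self.amplitudes, self.rates):
            y = y + a * np.exp(-k * t)
        return y


class FitError(RuntimeError):
    pass


def _mono(t, a, k, c):
    return a * np.exp(-k * t) + c


def fit_mono_decay(trace: KineticTrace, fixed_offset: float | None = None) -> DecayFit:
    """Least-squares fit of s(t) = a*exp(-k*t) + c.

    When the baseline is known independently — in relaxation measurements the
    fully relaxed absorbance is routinely recorded after the run — pass it as
    ``fixed_offset``; estimating one parameter fewer roughly halves the
    uncertainty on k.
    """
    t, s = trace.times, trace.signal
    if len(t) < 4:
        raise ValueError("mono-exponential fit requires at least 4 points")
    if np.ptp(s) == 0:
        raise FitError("signal is constant; no decay to fit")

    c0 = float(s[-1]) if fixed_offset is None else float(fixed_offset)
    a0 = float(s[0] - c0)
    if a0 == 0:
        a0 = float(np.ptp(s))
    # crude rate guess from the time to lose half the initial amplitude
    target = c0 + a0 / 2
    crossing = np.flatnonzero((s - target) * np.sign(a0) <= 0)
    t_half_guess = t[crossing[0]] if len(crossing) and crossing[0] > 0 else t[-1] / 2
    k0 = LN2 / max(t_half_guess, (t[1] - t[0]))
    try:
        if fixed_offset is None:
            popt, pcov = curve_fit(_mono, t, s, p0=[a0, k0, c0], maxfev=10000, method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13)
            a, k, c = popt
        else:
            f = lambda tt, a, k: _mono(tt, a, k, fixed_offset)  # noqa: E731
            (a, k), pcov = curve_fit(f, t, s, p0=[a0, k0], maxfev=10000, method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13)
            c = fixed_offset
            popt = (a, k, c)
    except RuntimeError as exc:
        raise FitError(f"mono-exponential fit did not converge: {exc}") from exc
    if k <= 0:
        raise FitError(f"mono-exponential fit produced non-positive rate k = {k}")
    sse = float(np.sum((s - _mono(t, *popt)) ** 2))
    return DecayFit(DecayModel.mono, (float(k),), (float(a),), float(c), pcov, sse, len(t))


def _bi(t, a1, ka, a2, kb, c):
    return a1 * np.exp(-ka * t) + a2 * np.exp(-kb * t) + c


def fit_bi_decay(trace: KineticTrace, rate_ratio_floor: float = 3.0) -> DecayFit:
    """Parallel bi-exponential fit s(t) = a1*exp(-ka*t) + a2*exp(-kb*t) + c.

    Initialization scans a log-spaced grid of (ka, kb) pairs with amplitudes
    solved linearly, then refines with nonlinear least squares.  If the two
    rates are indistinguishable (ka/kb below ``rate_ratio_floor``) or the
    corrected AIC prefers the mono model, the mono fit is returned with a
    warning.
    """
    t, s = trace.times, trace.signal
    if len(t) < 8:
        raise ValueError("bi-exponential fit requires at least 8 points")
    if np.ptp(s) == 0:
        raise FitError("signal is constant; no decay to fit")

    span = t[-1] - t[0]
    dt = float(np.min(np.diff(t)))
    k_grid = np.geomspace(0.05 / span, 2.0 / dt, 25)
    best = None
    for i, ka in enumerate(k_grid):
        ea = np.exp(-ka * t)
        for kb in k_grid[:i]:
            design = np.column_stack([ea, np.exp(-kb * t), np.ones_like(t)])
            coef, *_ = np.linalg.lstsq(design, s, rcond=None)
            sse = float(np.sum((s - design @ coef) ** 2))
            if best is None or sse < best[0]:
                best = (sse, ka, kb, coef)
    assert best is not None
    _, ka0, kb0, coef0 = best
    p0 = [coef0[0], ka0, coef0[1], kb0, coef0[2]]
    try:
        popt, pcov = curve_fit(_bi, t, s, p0=p0, maxfev=20000, method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13)
        a1, ka, a2, kb, c = popt
        if ka < kb:  # enforce fast-then-slow ordering
            a1, a2, ka, kb = a2, a1, kb, ka
        ok = ka > 0 and kb > 0
    except RuntimeError:
        ok = False

    mono = fit_mono_decay(trace)
    if not ok:
        warnings.warn("bi-exponential refinement failed; returning mono fit", RuntimeWarning)
        return mono
    sse = float(np.sum((s - _bi(t, a1, ka, a2, kb, c)) ** 2))
    bi = DecayFit(
        DecayModel.bi,
        (float(ka), float(kb)),
        (float(a1), float(a2)),
        float(c),
        pcov,
        sse,
        len(t),
    )
    if ka / kb < rate_ratio_floor:
        warnings.warn(
            f"rates indistinguishable (ratio {ka / kb:.2f} < {rate_ratio_floor}); "
            "falling back to mono-exponential",
            RuntimeWarning,
        )
        return mono
    if mono.aicc <= bi.aicc:
        warnings.warn("corrected AIC prefers the mono-exponential model", RuntimeWarning)
        return mono
    return bi


def fit_decay(trace: KineticTrace, model: str = "auto") -> DecayFit:
    """Fit a decay trace with the requested model ("mono", "bi" or "auto")."""
    if model == "mono":
        return fit_mono_decay(trace)
    if model in ("bi", "auto"):
        try:
            return fit_bi_decay(trace)
        except ValueError:
            if model == "auto":
                return fit_mono_decay(trace)
            raise
    raise ValueError(f"unknown decay model {model!r}")


def halflife_report(fit: DecayFit, T: Temperature) -> tuple[HalfLife, BarrierEstimate]:
    """Half-life of the slowest phase and its Eyring activation free energy."""
    k_slow = min(fit.rates)
    if fit.model is DecayModel.bi:
        logger.info("bi-exponential fit: reporting the slow phase (k = %.3g /s)", k_slow)
    t_half = HalfLife(LN2 / k_slow)
    return t_half, barrier_from_halflife(t_half, T)
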