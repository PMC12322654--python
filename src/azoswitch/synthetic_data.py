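"""Synthetic conformer ensembles, spectra and kinetic traces with known truth.

These generators emulate the inputs of the characterization pipeline —
thermally sampled conformer ensembles with per-snapshot vertical excitations,
measured UV-vis spectra, irradiation time courses and decay traces — with
every ground-truth parameter planted and recorded, so that each analysis
module can be validated by parameter recovery.

The conformer generator samples the azo dihedrals (psi around N=N, phi
around each C-N bond) from wrapped-normal distributions, embeds them in an
idealized 24-atom azobenzene scaffold (C-C 1.39, N=N 1.25, C-N 1.42
angstrom, sp2 angles; adequate for dihedral extraction, not for energetics)
and assigns each snapshot a vertical excitation energy

    E = E0 - beta * para_weight * planarity - psi_coupling * (1+cos psi)/2 + noise

where planarity = (|cos phi1| + |cos phi2|)/2 is 1 for rings coplanar with
the C-N=N unit.  A positive beta encodes the red-shift of in-plane
configurations; para_weight amplifies it, emulating the resonance coupling
of an electron-withdrawing para substituent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .ensemble_spectra import EnsembleSpectrum, ExperimentalSpectrum, to_wavelength
from .photokinetics import (
    IsomerRatio,
    KineticTrace,
    PhotokineticModel,
    simulate_photoswitching,
)
from .trajectory_features import Frame

__all__ = [
    "CompoundProfile",
    "PROFILES",
    "build_azobenzene_frame",
    "gen_ensemble",
    "gen_trace",
    "gen_experimental_spectrum",
    "GSH_BI_PRESET",
]


@dataclass(frozen=True)
class CompoundProfile:
    """Ground-truth parameters of a synthetic azobenzene-like compound."""

    name: str
    e0_trans: float  # base vertical excitation energy, eV
    e0_cis: float
    beta: float  # planarity -> energy coupling, eV
    para_weight: float = 1.0  # electron-withdrawing amplification of beta
    psi_coupling: float = 0.02  # eV
    phi_mean_deg: float = 0.0  # mean ring twist
    phi_spread_deg: float = 15.0
    psi_spread_deg: float = 6.0
    noise_sd: float = 0.05  # eV
    f_mean: float = 0.02  # oscillator strength of the n->pi* band
    f_sd: float = 0.005

    def __post_init__(self) -> None:
        for field_name in ("e0_trans", "e0_cis", "phi_spread_deg", "psi_spread_deg", "f_mean"):
            if not getattr(self, field_name) > 0:
                raise ValueError(f"{field_name} must be positive")
        for field_name in ("noise_sd", "f_sd", "beta", "para_weight"):
            if getattr(self, field_name) < 0:
                raise ValueError(f"{field_name} must be >= 0")


#: Three shipped presets spanning the flexibility/coupling range of the
#: studied substitution patterns: a rigid near-planar parent azobenzene, a
#: floppy ortho-halogenated scaffold, and the same scaffold with an
#: electron-withdrawing para ester that doubles the planarity coupling.
PROFILES: dict[str, CompoundProfile] = {
    "azobenzene-like": CompoundProfile(
        name="azobenzene-like",
        e0_trans=2.72,
        e0_cis=2.76,
        beta=0.05,
        para_weight=1.0,
        phi_mean_deg=0.0,
        phi_spread_deg=12.0,
        psi_spread_deg=6.0,
    ),
    "dfdc-like": CompoundProfile(
        name="dfdc-like",
        e0_trans=2.50,
        e0_cis=2.85,
        beta=0.12,
        para_weight=1.0,
        phi_mean_deg=30.0,
        phi_spread_deg=35.0,
        psi_spread_deg=8.0,
    ),
    "dfdc-ester-like": CompoundProfile(
        name="dfdc-ester-like",
        e0_trans=2.45,
        e0_cis=2.82,
        beta=0.12,
        para_weight=2.0,
        phi_mean_deg=30.0,
        phi_spread_deg=35.0,
        psi_spread_deg=8.0,
    ),
}

# idealized internal coordinates, angstrom / degrees
_R_NN = 1.25
_R_CN = 1.42
_R_CC = 1.39
_R_CH = 1.08
_ANG_CNN = 114.0
_ANG_RING = 120.0


def _nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta_deg: float, tau_deg: float) -> np.ndarray:
    """Place atom d given bond r = |cd|, angle theta = b-c-d and torsion
    tau = a-b-c-d (same sign convention as trajectory_features.dihedral)."""
    theta = math.radians(theta_deg)
    tau = math.radians(tau_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("reference atoms are collinear; torsion undefined")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(tau),
            r * math.sin(theta) * math.sin(tau),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_azobenzene_frame(
    psi_deg: float,
    phi1_deg: float,
    phi2_deg: float,
    frame_index: int = 0,
) -> Frame:
    """Idealized 24-atom azobenzene geometry with the given torsions imposed.

    Atom order (1-based): N1, N2, C-ipso-A, C-ipso-B, ring A carbons
    (ortho, meta, para, meta, ortho), ring B carbons likewise, then the ten
    ring hydrogens.  psi is the C3-N1=N2-C4 torsion; phi1/phi2 are the
    C(ortho)-C(ipso)-N=N torsions of rings A and B.
    """
    coords = np.zeros((24, 3))
    n1 = np.array([0.0, 0.0, 0.0])
    n2 = np.array([_R_NN, 0.0, 0.0])
    ang = math.radians(_ANG_CNN)
    c1 = n1 + _R_CN * np.array([math.cos(ang), math.sin(ang), 0.0])
    c2 = _nerf_place(c1, n1, n2, _R_CN, _ANG_CNN, psi_deg)

    def ring(c_ipso, n_near, n_far, phi):
        """Five remaining ring carbons, built off the ipso carbon."""
        ca2 = _nerf_place(n_far, n_near, c_ipso, _R_CC, _ANG_RING, phi)
        ca6 = _nerf_place(n_far, n_near, c_ipso, _R_CC, _ANG_RING, phi + 180.0)
        ca3 = _nerf_place(n_near, c_ipso, ca2, _R_CC, _ANG_RING, 180.0)
        ca4 = _nerf_place(c_ipso, ca2, ca3, _R_CC, _ANG_RING, 0.0)
        ca5 = _nerf_place(ca2, ca3, ca4, _R_CC, _ANG_RING, 0.0)
        return ca2, ca3, ca4, ca5, ca6

    ring_a = ring(c1, n1, n2, phi1_deg)
    ring_b = ring(c2, n2, n1, phi2_deg)

    coords[0], coords[1], coords[2], coords[3] = n1, n2, c1, c2
    coords[4:9] = ring_a
    coords[9:14] = ring_b

    # in-plane hydrogens pointing away from each ring centroid
    center_a = np.mean(np.vstack([c1, *ring_a]), axis=0)
    center_b = np.mean(np.vstack([c2, *ring_b]), axis=0)
    h = 14
    for atoms, center in ((ring_a, center_a), (ring_b, center_b)):
        for ca in atoms:
            out = ca - center
            coords[h] = ca + _R_CH * out / np.linalg.norm(out)
            h += 1

    symbols = ["N", "N"] + ["C"] * 12 + ["H"] * 10
    return Frame(
        symbols,
        coords,
        frame_index=frame_index,
        comment=f"synthetic azobenzene psi={psi_deg:.4f} phi1={phi1_deg:.4f} phi2={phi2_deg:.4f}",
    )


def _wrap_deg(angle: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180]."""
    wrapped = np.mod(angle + 180.0, 360.0) - 180.0
    wrapped[wrapped == -180.0] = 180.0
    return wrapped


def gen_ensemble(
    profile: CompoundProfile,
    isomer: str = "trans",
    n: int = 6000,
    seed: int = 0,
    build_frames: bool = True,
) -> tuple[list[Frame], pd.DataFrame]:
    """Sample a conformer ensemble with planted dihedral -> energy structure.

    Returns the geometries (empty list when ``build_frames=False``) and an
    excitation table carrying the true dihedrals, their transforms and the
    planted planarity feature, so downstream feature extraction and
    correlation analysis can be cross-validated against the truth.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    if isomer not in ("cis", "trans"):
        raise ValueError(f"isomer must be 'cis' or 'trans', got {isomer!r}")
    rng = np.random.default_rng(seed)

    psi_mean = 180.0 if isomer == "trans" else 8.0
    psi = _wrap_deg(rng.normal(psi_mean, profile.psi_spread_deg, n))
    sign1 = rng.choice([-1.0, 1.0], n)
    sign2 = rng.choice([-1.0, 1.0], n)
    phi1 = _wrap_deg(rng.normal(sign1 * profile.phi_mean_deg, profile.phi_spread_deg, n))
    phi2 = _wrap_deg(rng.normal(sign2 * profile.phi_mean_deg, profile.phi_spread_deg, n))

    cos_psi = np.cos(np.radians(psi))
    abs_cos_phi1 = np.abs(np.cos(np.radians(phi1)))
    abs_cos_phi2 = np.abs(np.cos(np.radians(phi2)))
    planarity = 0.5 * (abs_cos_phi1 + abs_cos_phi2)

    e0 = profile.e0_trans if isomer == "trans" else profile.e0_cis
    energy = (
        e0
        - profile.beta * profile.para_weight * planarity
        - profile.psi_coupling * 0.5 * (1.0 + cos_psi)
        + rng.normal(0.0, profile.noise_sd, n)
    )
    if profile.f_sd > 0:
        lo = -profile.f_mean / profile.f_sd
        strength = truncnorm.rvs(lo, np.inf, loc=profile.f_mean, scale=profile.f_sd, size=n, random_state=rng)
    else:
        strength = np.full(n, profile.f_mean)

    table = pd.DataFrame(
        {
            "frame": np.arange(n),
            "isomer": isomer,
            "energy_eV": energy,
            "osc_strength": strength,
            "psi_deg": psi,
            "phi1_deg": phi1,
            "phi2_deg": phi2,
            "cos_psi": cos_psi,
            "abs_cos_phi1": abs_cos_phi1,
            "abs_cos_phi2": abs_cos_phi2,
            "planarity": planarity,
        }
    )
    frames: list[Frame] = []
    if build_frames:
        frames = [
            build_azobenzene_frame(psi[i], phi1[i], phi2[i], frame_index=i) for i in range(n)
        ]
    return frames, table


@dataclass
class QuantumYieldExperiment:
    """A synthetic quantum-yield measurement with its planted truth."""

    trace: KineticTrace  # absorbance at the analysis wavelength vs time
    anchors: list[tuple[float, IsomerRatio]]
    photon_flux_einstein_per_s: float
    volume_liters: float
    absorbance_irr: float
    total_conc: float
    phi_true: float
    conversion_window: float  # recommended initial-rate window


def gen_quantum_yield_experiment(
    phi_tc: float = 0.00446,
    noise_sd: float = 0.002,
    seed: int = 0,
    clean_cis_fraction: KineticTrace | None = None,
) -> QuantumYieldExperiment:
    """Emulate a 650 nm quantum-yield run on a weakly absorbing photoswitch.

    Conditions mirror a typical determination: 500 uM sample in a 2 mL,
    1 cm cuvette; ~0.6 nmol photons/s of deep-red light absorbed through a
    tail absorbance of A = 0.0175; absorbance followed at the cis-band
    analysis wavelength (contrast 0.10 -> 0.40 AU across full conversion)
    every second early on and every 100 s out to full conversion; four NMR
    anchor ratios spread over the conversion.  ``noise_sd`` is the absorbance
    noise in AU.  Pass ``clean_cis_fraction`` to reuse the (deterministic)
    integrated time course across seeds.
    """
    q_p = 6.08e-7  # einstein/s delivered
    volume = 0.002  # L
    conc = 5e-4  # mol/L
    model = PhotokineticModel(
        phi_tc=phi_tc,
        phi_ct=0.01,
        eps_t=35.0,
        eps_c=2.0,
        photon_flux=q_p / volume,
        path_length=1.0,
        k_thermal=0.0,
        total_conc=conc,
    )
    if clean_cis_fraction is None:
        clean_cis_fraction = simulate_photoswitching(
            model, [(40000.0, True)], points_per_segment=4000
        )
    times = np.concatenate([np.arange(0.0, 2000.0, 1.0), np.arange(2000.0, 40000.0, 100.0)])
    x = np.interp(times, clean_cis_fraction.times, clean_cis_fraction.signal)
    a_trans, a_cis = 0.10, 0.40
    rng = np.random.default_rng(seed)
    absorbance = a_trans * (1 - x) + a_cis * x + rng.normal(0.0, noise_sd, times.shape)
    trace = KineticTrace(times, absorbance, signal_kind="absorbance")
    anchor_times = [0.0, 5000.0, 15000.0, 39000.0]
    anchors = [
        (t, IsomerRatio.from_cis(float(np.interp(t, clean_cis_fraction.times, clean_cis_fraction.signal))))
        for t in anchor_times
    ]
    trace.metadata["truth"] = {"phi_tc": phi_tc, "model": model, "noise_sd": noise_sd}
    trace.metadata["clean_cis_fraction"] = clean_cis_fraction
    return QuantumYieldExperiment(
        trace=trace,
        anchors=anchors,
        photon_flux_einstein_per_s=q_p,
        volume_liters=volume,
        absorbance_irr=model.absorbance_irr(0.0),
        total_conc=conc,
        phi_true=phi_tc,
        conversion_window=0.15,
    )


#: canonical bi-exponential preset: half-lives of 20 min and 160 min
GSH_BI_PRESET = {
    "k_fast": math.log(2) / (20 * 60.0),
    "k_slow": math.log(2) / (160 * 60.0),
    "a_fast": 0.5,
    "a_slow": 0.5,
    "offset": 0.0,
}


def gen_trace(
    kind: str,
    params: dict,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KineticTrace:
    """Generate a kinetic trace of the requested kind with seeded noise.

    kinds:
      - ``"mono"``: params k, amplitude (default 1), offset (default 0)
      - ``"bi"``: params k_fast, k_slow, a_fast, a_slow, offset
      - ``"photoswitch"``: params model (PhotokineticModel), schedule, x0

    The exact ground-truth parameters are embedded in ``metadata["truth"]``.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    if kind == "mono":
        k = params["k"]
        a = params.get("amplitude", 1.0)
        c = params.get("offset", 0.0)
        clean = a * np.exp(-k * times) + c
        trace = KineticTrace(times, clean + rng.normal(0, noise_sd, times.shape))
    elif kind == "bi":
        clean = (
            params["a_fast"] * np.exp(-params["k_fast"] * times)
            + params["a_slow"] * np.exp(-params["k_slow"] * times)
            + params.get("offset", 0.0)
        )
        trace = KineticTrace(times, clean + rng.normal(0, noise_sd, times.shape))
    elif kind == "photoswitch":
        model: PhotokineticModel = params["model"]
        sim = simulate_photoswitching(
            model,
            params["schedule"],
            params.get("x0", IsomerRatio(1.0, 0.0)),
            points_per_segment=params.get("points_per_segment", 100),
        )
        sig = np.interp(times, sim.times, sim.signal)
        trace = KineticTrace(
            times,
            sig + rng.normal(0, noise_sd, times.shape),
            signal_kind="cis_fraction",
        )
    else:
        raise ValueError(f"unknown trace kind {kind!r}")
    trace.metadata["truth"] = {"kind": kind, **params, "noise_sd": noise_sd, "seed": seed}
    return trace


def gen_experimental_spectrum(
    spectrum: EnsembleSpectrum,
    shift_ev: float = 0.0,
    scale: float = 1.0,
    baseline_sd: float = 0.0,
    multiplicative_sd: float = 0.0,
    seed: int = 0,
    concentration: float = 5e-4,
    path_length: float = 1.0,
    wavelength_grid: np.ndarray | None = None,
) -> ExperimentalSpectrum:
    """Turn an ensemble spectrum into a noisy 'measured' wavelength trace.

    The spectrum is shifted by ``shift_ev`` (emulating the systematic error a
    real calculation would carry relative to experiment), scaled, resampled
    onto a uniform nanometer grid, and perturbed with additive baseline noise
    and/or multiplicative amplitude noise.  Beer-Lambert metadata defaults to
    the standard measurement condition (500 uM, 1 cm).
    """
    trace = to_wavelength(spectrum.shifted(shift_ev))
    if wavelength_grid is None:
        wavelength_grid = np.arange(300.0, 801.0, 1.0)
    rng = np.random.default_rng(seed)
    y = scale * np.interp(wavelength_grid, trace.wavelength_nm, trace.intensity, left=0.0, right=0.0)
    if multiplicative_sd > 0:
        y = y * (1.0 + rng.normal(0, multiplicative_sd, y.shape))
    if baseline_sd > 0:
        y = y + rng.normal(0, baseline_sd, y.shape)
    return ExperimentalSpectrum(
        wavelength_grid, y, concentration=concentration, path_length=path_length
    )
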