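# Methods

This note documents the models implemented in `azoswitch`, the choices made
where the design was genuinely open, and what the synthetic-data generators
do and do not emulate.

## Eyring thermokinetics

Thermal cis→trans relaxation of an azobenzene is first-order, so a measured
half-life t½ at temperature T fixes the rate k = ln2/t½ and, through the
Eyring equation

    k = κ (k_B T / h) exp(−ΔG‡ / RT),        κ = 1,

the activation free energy ΔG‡ = RT ln(k_B T / (h k)). Constants are CODATA
2018; R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹; the transmission coefficient is
fixed at 1, the standard assumption for a thermally activated isomerization.
"Room temperature" is taken as 298.15 K; Celsius→Kelvin adds exactly 273.15.
Mixed time units (s, min, h, d, y) are parsed with 1 y = 365.25 d.

Inverting the twenty measured half-lives in `compounds.py` reproduces the
reported experimental barriers to the printed decimal for nineteen of the
twenty compounds. Compound 38 is the exception: its reported 23.3 kcal/mol
is inconsistent with single-point inversion of its own measured half-life
(52.2 min at 60 °C inverts to 25.1); the package flags, and does not
resolve, the discrepancy.

**Temperature extrapolation.** A single-temperature measurement cannot
separate ΔH‡ from ΔS‡, so `extrapolate_halflife` assumes by default that ΔG‡
is temperature-independent: invert at the measured temperature, re-evaluate
at the target. An alternative Arrhenius mode (fixed pre-exponential, default
10¹³ s⁻¹, temperature-independent E_a) is available behind a flag; the two
assumptions genuinely differ and neither can be validated from one
temperature. Constant-ΔG‡ chaining gives ≈182 h at 298.15 K for the parent
azobenzene's 3.16 h at 55 °C, which does not match the published
room-temperature extrapolation (211 h); the published extrapolation method
is not specified at the level implemented here, and the package makes no
claim to reproduce that column.

Note on printed precision: a barrier rounded to one decimal (±0.05 kcal/mol)
maps through exp(±0.05/RT) to a ±8.8% band on the half-life at 298 K. Tests
of barrier→half-life inversion against printed values use that bound, not a
tighter one.

## Dihedral features

The flexibility analysis uses ψ, the C–N=N–C torsion around the central
bond, and φ, the C(ortho)–C(ipso)–N=N torsion of each aryl ring. Torsions
follow the IUPAC sign convention, are reported in degrees in (−180, 180],
and are invariant under rigid motion and under reversal of the atom
sequence. Because the two ortho carbons of an aryl ring are equivalent, φ is
physically defined only modulo 180°; all derived features (|cos φ|, |sin φ|)
respect that symmetry, and consistency checks compare φ modulo 180°.

The literature uses two incompatible phase conventions for φ — planar rings
described both as |cos φ| = 1 and as cos φ = 0, depending on which atoms
define the torsion. Rather than guessing, the feature table emits **both**
transforms (`abs_cos_phi*` and `abs_sin_phi*`) with self-describing column
names. With the C(ortho)–C(ipso)–N=N definition used here, a ring coplanar
with the C–N=N unit has φ = 0 or 180°, i.e. |cos φ| = 1.

ψ/φ atom indices for azobenzene-like topologies are auto-detected (N=N by
element and distance < 1.4 Å, then the bonded ipso and ortho carbons);
explicit specs always override. Indices are 1-based in user-facing
interfaces, 0-based internally. XYZ I/O is a minimal multi-frame reader/
writer (count line, comment line, atom lines); comments are preserved as
frame metadata.

## Nuclear-ensemble spectra

A spectrum is assembled from N vertical excitations (Eᵢ, fᵢ) as

    I(E) = (1/N) Σᵢ fᵢ G(E − Eᵢ; fwhm),

with G a unit-area Gaussian. Defaults: FWHM 0.15 eV (chosen to give
realistic visible-band widths; exposed in config), grid 1.5–4.5 eV at 2 meV.
The integral of I equals the mean oscillator strength exactly (absolute
cross-section prefactor documented as 1); this conservation property is a
test invariant. Wavelength conversion uses hc = 1239.842 eV·nm; the
E²-Jacobian density correction is off by default, matching common
ensemble-spectrum plotting practice, and available behind a flag (it moves a
broad band's maximum blueward by ≈2σ²/E₀).

**Shift calibration.** Computed excitation energies carry a systematic
error, removed by fitting a single energy shift plus an amplitude scale
(computed intensities are relative) that minimize the least-squares
difference to an experimental trace inside a wavelength window (default
380–780 nm, the visible n→π* region). The scale is solved in closed form at
each candidate shift; the shift is scanned on a 1 meV grid over ±0.5 eV with
3-point parabolic refinement. Recovery of planted shifts is exact to the
scan step at zero noise and within a few meV at 5% amplitude noise.

**Band metrics.** λ_max by argmax with 3-point parabolic refinement;
the band-tail extent is the longest wavelength in the window where intensity
stays at or above a threshold fraction (default 1%) of the peak, with linear
interpolation of the crossing — operationally, the longest wavelength at
which photoswitching is still productive. Molar absorptivity follows
Beer–Lambert, ε = A/(c·l), in L mol⁻¹ cm⁻¹.

## Flexibility correlations

Plain product-moment (Pearson) correlation matrices between per-frame
features and photo-properties. Missing rows are handled pairwise-complete
with logged counts; constant columns give *undefined* (NaN) correlations,
never zero. No p-values are attached — the analysis reports effect sizes
only. Matrix ordering is fixed (energy, strength, cos ψ, |cos φ₁|,
|cos φ₂|, extras) so heatmaps are comparable across compounds. Heatmaps use
a diverging scale centered at zero spanning [−1, 1].

## Photokinetics

Two-state model under monochromatic irradiation. With cis fraction x_c,
total concentration C, path l, volumetric photon flux I₀ (einstein L⁻¹ s⁻¹)
and absorbance A = (ε_t(1−x_c) + ε_c x_c) C l at the irradiation wavelength:

    dx_c/dt = (I₀/C)(1 − 10^(−A)) [ f_t Φ_tc − f_c Φ_ct ] − k_th x_c,

where f_i = ε_i c_i l / A is the fraction of absorbed photons captured by
isomer i. Dark segments use the exact exponential; lit segments an adaptive
LSODA integration (rtol 1e-9). An `optically_thin` option replaces
1 − 10^(−A) by A ln10.

**Photostationary state.** With k_th = 0 the absorption nonlinearity cancels
and x_c(PSS) = ε_tΦ_tc / (ε_tΦ_tc + ε_cΦ_ct) exactly. With thermal
relaxation the closed form solves the optically thin balance,
x_c = a/(a + b + k_th) with a = I₀ ln10 l ε_tΦ_tc, b = I₀ ln10 l ε_cΦ_ct;
it agrees with the thin-ODE steady state to 1e-6 and with the exact ODE to
O(A) when A is small.

**Quantum-yield estimator.** Reconstructed as an initial-rate method
anchored by NMR composition measurements: (1) the absorbance at the analysis
wavelength is mapped linearly onto the cis fraction via least squares
through the anchor (time, trans:cis) pairs — at least two anchors spanning
the conversion are required; (2) the initial conversion rate dx_c/dt|₀ is
taken from a fit over the early window (default: up to 10% conversion beyond
the start); (3) Φ_tc = n_total · dx_c/dt|₀ / (q_p (1 − 10^(−A_irr)) f_t,0),
with q_p the delivered photon rate and f_t,0 the trans share of absorption
at t→0 (1 for a dark-adapted start). The initial-rate fit is a quadratic in
time whose linear coefficient is reported: the conversion rate declines
measurably across even a 10–15% window (trans depletion, falling absorbed
photon rate, back-reaction), and a straight line through the window
underestimates the t=0 slope by roughly half the window width (−5.6% in a
simulated run at the 10% window), while the quadratic removes the bias
(mean −0.5%, worst 3.8% over 100 noise realizations of the reference
synthetic experiment). A linear fit is used when the window holds fewer
than 10 points.

**Decay fitting.** Mono: s(t) = a e^(−kt) + c by nonlinear least squares
(trust-region reflective, tolerances 1e-13 — the default Levenberg–Marquardt
stalls near 1e-8 on these parameter scales). When the baseline is known
independently — fully relaxed absorbance recorded after the run, routine in
relaxation measurements — it can be fixed, which roughly halves the
uncertainty on k; with a free offset the information bound on the rate at 50
points and SNR 50 is ≈2.5% regardless of span. Bi:
s(t) = a₁e^(−k_a t) + a₂e^(−k_b t) + c with k_a > k_b, initialized by a
log-spaced (k_a, k_b) grid with amplitudes solved linearly, refined by least
squares. Model selection against mono uses corrected AIC; rate ratios below
3 fall back to mono with a warning. The two-phase degradation is modelled as
a *parallel* biexponential; a sequential A→B→C scheme produces the identical
two-exponential functional form with reinterpreted amplitudes, so the fitted
rates and half-lives are scheme-independent and no separate fitter is
needed. Reported half-lives use the slowest phase; `halflife_report` bridges
a fit directly to an Eyring barrier.

## Synthetic data: what it emulates, and what it does not

`gen_ensemble` emulates a thermally sampled conformer ensemble with
per-snapshot vertical excitations. Dihedrals are drawn from wrapped-normal
distributions (chosen over von Mises for simpler quantile control; at the
spreads used the two are nearly indistinguishable), embedded in an idealized
24-atom azobenzene scaffold (C–C 1.39 Å, N=N 1.25 Å, C–N 1.42 Å, sp²
angles) built by internal-coordinate (NeRF) placement so the sampled
torsions are imposed exactly. The excitation energy follows

    E = E₀ − β·w_para·planarity − γ(1 + cos ψ)/2 + ε,   ε ~ N(0, σ),

with planarity = (|cos φ₁| + |cos φ₂|)/2. A positive β encodes the
red-shift of in-plane ring configurations (π* delocalization requires
planarity); w_para amplifies it, emulating the resonance coupling of an
electron-withdrawing para substituent. Oscillator strengths are truncated
normal (≥0). Default ensemble size is 6000 snapshots.

Three presets span the studied substitution patterns:

| preset | φ mean/spread | β (eV) | w_para | reading |
|---|---|---|---|---|
| azobenzene-like | 0° / 12° | 0.05 | 1.0 | rigid, near-planar parent |
| dfdc-like | 30° / 35° | 0.12 | 1.0 | floppy ortho-halogenated scaffold |
| dfdc-ester-like | 30° / 35° | 0.12 | 2.0 | + electron-poor para ester |

Energy noise σ = 0.05 eV throughout. These choices produce
r(E, planarity) ≈ −0.03 / −0.43 / −0.68 respectively at n = 6000, i.e. the
correlation strengthens with flexibility and with electron-withdrawing
coupling — the qualitative ordering the analysis is meant to detect. The
base energies place the trans n→π* band red of the cis band for the
ortho-substituted presets, so synthetic cis/trans band splits are positive.

The generator is a statistical surrogate, not an electronic-structure model:
bond lengths are idealized, the energy model is linear in the planarity
feature, there is no Boltzmann reweighting, no vibronic structure and no
solvent. Passing tests therefore demonstrate that the *analysis chain*
(geometry → features → correlation → spectra → calibration → kinetics)
recovers planted structure at realistic noise; they say nothing about the
accuracy of any particular electronic-structure method on real compounds.

`gen_trace` produces mono-/bi-exponential decays (the canonical bi preset
uses half-lives of 20 min and 160 min, the reported two-step degradation of
the nitro-substituted cis isomer in the presence of glutathione) and
photoswitching time courses via the ODE above, each with seeded Gaussian
noise and the truth embedded in metadata. `gen_quantum_yield_experiment`
wraps a full synthetic determination: 500 µM sample, 2 mL, 1 cm path,
6.08×10⁻⁷ einstein/s delivered at a tail absorbance of 0.0175 (values
representative of deep-red irradiation of a weakly absorbing switch),
absorbance followed at 1 s intervals early and 100 s intervals to full
conversion, with four NMR anchors across the conversion. The recommended
initial-rate window for this design is 15% conversion (with the quadratic
fit; see above).

**Problem sizes.** The test suite and the acceptance script use ensembles of
up to 6000 snapshots (geometry building is restricted to a few hundred
frames where Cartesian coordinates are actually consumed), 100 noise
realizations for shift-calibration and decay-recovery studies, and 10
replicates for the quantum-yield study; these sizes give sampling errors
comfortably below the tolerances being checked while keeping the default
run in the minutes range.

## Known limitations

- ΔH‡/ΔS‡ cannot be decomposed from the single-temperature data the package
  targets; extrapolations inherit the constant-ΔG‡ (or fixed-prefactor)
  assumption.
- The ensemble-spectrum prefactor is relative; absolute cross sections are
  out of scope.
- The quantum-yield estimator assumes the analysis-wavelength absorbance is
  linear in composition (isosbestic-free two-state system) and monochromatic
  irradiation.
- Auto-detection of azo dihedrals assumes one N=N unit and standard bond
  lengths; unusual topologies need explicit atom indices.
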