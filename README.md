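# azoswitch

Characterization toolkit for azobenzene photoswitches — the chromophores
behind red-light-operated optical tools and photopharmaceuticals. Designing
a switch for the bio-optical window (650–950 nm) requires juggling four
quantities: where the n→π* band sits and how far its tail extends, how fast
the metastable cis isomer relaxes in the dark, how efficiently photons drive
isomerization, and whether the compound survives intracellular reductants
such as glutathione. `azoswitch` implements the analysis layer for all four,
plus seeded synthetic-data generators with planted ground truth so every
estimator can be validated by parameter recovery.

## What it computes

**Thermokinetics** — the Eyring equation k = κ(k_BT/h)·exp(−ΔG‡/RT) links a
measured cis→trans relaxation half-life t½ = ln2/k to an activation free
energy ΔG‡, and back. Includes temperature extrapolation (constant-ΔG‡ by
default, Arrhenius behind a flag), mixed time-unit parsing (s…years), and a
bundled table of measured half-lives and reported barriers for twenty
characterized switches.

**Nuclear-ensemble spectra** — broadened UV–vis spectra from ensembles of
vertical excitations, I(E) = (1/N)·Σ fᵢ·G(E−Eᵢ; fwhm); systematic-shift
calibration against experimental traces; λ_max, cis/trans band separation
and band-tail extent; Beer–Lambert molar absorptivities.

**Dihedral flexibility** — multi-frame XYZ ingestion, ψ (N=N torsion) and φ
(C–N ring torsions) extraction with both cosine-transform conventions, and
Pearson correlation matrices between structural features and
photo-properties.

**Photokinetics** — a two-state irradiation ODE with Beer–Lambert photon
absorption, closed-form photostationary states, an NMR-anchored initial-rate
quantum-yield estimator, and mono-/bi-exponential decay fitting with
AIC-based model selection.

**Synthetic data** — conformer ensembles with a planted dihedral→energy
coupling embedded in real 24-atom geometries, noisy "experimental" spectra,
and kinetic traces, all bit-reproducible given a seed.

## Worked example

```python
from azoswitch import *

# measured: dfdc azobenzene, cis half-life 3.7 h at 90 C
est = barrier_from_halflife(HalfLife.parse("3.7 h"), Temperature.from_celsius(90))
print(f"dG = {est.delta_g:.3f} kcal/mol")
rt = extrapolate_halflife(HalfLife.parse("3.7 h"),
                          Temperature.from_celsius(90), Temperature.room())
print(f"t1/2(298 K) = {rt.human()}")

# synthetic conformer ensemble with an electron-poor para substituent
frames, table = gen_ensemble(PROFILES["dfdc-ester-like"], "trans",
                             n=6000, seed=1, build_frames=False)
spec = assemble_spectrum(table)                  # Gaussian FWHM 0.15 eV
m = band_metrics(to_wavelength(spec))
print(f"lambda_max = {m.lambda_max:.1f} nm, tail = {m.tail_extent:.1f} nm")
mat = pearson_matrix(table, columns=["energy_eV", "planarity"])
print(f"r(E, planarity) = {mat.get('energy_eV', 'planarity'):.3f}")
```

prints

```
dG = 28.519 kcal/mol
t1/2(298 K) = 2.84 y
lambda_max = 547.1 nm, tail = 620.1 nm
r(E, planarity) = -0.679
```

Reading: the 3.7 h half-life at 90 °C corresponds to a 28.5 kcal/mol
barrier, i.e. a near-bistable switch that would take years to relax at room
temperature. In the synthetic ensemble the excitation energy correlates
strongly and negatively with ring planarity — in-plane conformations
red-shift the transition, and the correlation is strongest when an
electron-withdrawing para group couples the π systems.

The same operations are scriptable from the shell:

```bash
azoswitch barrier --t-half 3.7h --temp 90C
azoswitch simulate ensemble --profile dfdc-ester-like --n 6000 --seed 1 \
    --out-xyz traj.xyz --out-exc exc.csv
azoswitch dihedrals traj.xyz --out features.csv
azoswitch fit-decay trace.csv --model auto
```

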