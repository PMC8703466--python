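# specbind

Spectroscopic characterisation of protein–ligand binding from fluorescence
quenching, thermodynamic, time-resolved and circular-dichroism data.

The package was built around a concrete problem: quantifying how a small
hydrophobic ligand binds the nucleotide-binding domain (NBD) of HSP70, a
~40 kDa ATPase domain whose single tryptophan (Trp90) serves as an
intrinsic fluorescence probe. Everything it computes generalises to any
single-fluorophore protein titrated with an absorbing quencher.

## What it computes

**Quenching analysis.** Observed intensities are first corrected for the
inner-filter effect, F_corr = F_obs · 10^((a·A_ex + b·A_em)/10) with cuvette
factors (a, b) = (5, 1) by default. The Stern–Volmer law

    F0/F = 1 + K_SV[Q] = 1 + k_q·τ0·[Q]

is fitted by OLS per temperature; the quenching mechanism is classified as
*static* (ground-state complex) or *dynamic* (collisional) from three
criteria: K_SV decreasing with T, lifetime ratios τ0/τ ≈ 1 while F0/F
rises, and k_q above the diffusion limit (~10¹⁰ M⁻¹s⁻¹). The association
constant K_a and apparent stoichiometry n come from the double-log model
log((F0−F)/F) = n·log K_a + n·log[Q]_free with ligand depletion accounted
for.

**Thermodynamics.** Van't Hoff regression of ln K_a on 1/T yields ΔH and
ΔS with regression covariance; ΔG = ΔH − TΔS; the (ΔH, ΔS) sign pattern
labels the dominant driving force (van der Waals/H-bond, hydrophobic or
mixed, with an enthalpy–entropy "balanced" annotation).

**IDF / Scatchard / Hill.** The model-free Interaction Density Function
method compares titrations at two protein concentrations: equal fractional
quenching ΔF = |F−F0|/F0 implies equal free ligand and equal binding
density Σν, so mass conservation [L] = [L]_free + Σν·[P] at the two
concentrations is solved level-by-level for ([L]_free, Σν). A Scatchard
plot (Σν/[L]_free vs Σν) diagnoses cooperativity by concavity, and the
Hill isotherm Σν = n(K_b x)^h / (1 + (K_b x)^h) is fitted for the site
number n, binding constant K_b and Hill coefficient h.

**Lifetimes.** TCSPC histograms are tail-fitted with multiexponential
decays under Poisson weighting; the intensity-weighted average lifetime
τ_avg = Σα_iτ_i²/Σα_iτ_i feeds the mechanism test.

**CD melting.** Millidegree ellipticities convert to mean residue
ellipticity [θ] = θ/(10·[P]·l·n); a two-state sigmoid fitted to the thermal
scan yields the melting temperature Tm and the folded fraction
f = ([θ]_obs − [θ]_den)/([θ]_nat − [θ]_den).

**Synthetic experiments.** `specbind.simulate` contains exact forward
models for every estimator (cooperative binding with mass conservation and
static quenching, Van't Hoff-scaled constants, Poisson decay histograms,
two-state melts), so each analysis stage is verifiable by parameter
recovery.

## Worked example

```python
from specbind import vant_hoff_fit

res = vant_hoff_fit({283.0: 2.5e4, 293.0: 2.2e4, 303.0: 1.8e4})
print(res.summary())
```

```
Van't Hoff analysis
  dH     -11.68 +/- 1.73 kJ/mol
  dS      43.05 +/- 5.91 J/mol/K
  R^2   0.97854
  driving force: mixed (electrostatic or van der Waals), enthalpy-entropy balanced
  T (K)    dG (kJ/mol)       T*dS (kJ/mol)
   283.0    -23.86 +/- 0.07      12.18
   293.0    -24.29 +/- 0.05      12.61
   303.0    -24.72 +/- 0.08      13.04
```

The binding is exothermic (ΔH < 0) and spontaneous at all three
temperatures (ΔG < 0); because |ΔH| ≈ |TΔS| the enthalpic and entropic
contributions are balanced, the signature of van der Waals–dominated
complexation with solvent displacement.

A synthetic melting scan round-trips through the CD fit:

```python
from specbind import GroundTruth, simulate_melt, fit_melting

truth = GroundTruth()                 # Tm = 314 K, 1% noise
melt = simulate_melt(truth, rng=truth.rng(1))
print(fit_melting(melt).summary())
```

```
Two-state melting fit
  Tm           313.97 +/- 0.04 K
  width          2.54 +/- 0.03 K
  theta_nat      -20.02
  theta_den      -4.013
  R^2          0.999654
```

The same analyses are available from the shell:

```sh
specbind simulate titration --seed 3 --out sim.csv
specbind quench --titrations sim.csv --tau0 2.13e-9 --out quench.json
specbind thermo --ka 283:2.5e4 --ka 293:2.2e4 --ka 303:1.8e4 --out thermo.json
```

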