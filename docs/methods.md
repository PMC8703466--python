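# Methods

This note documents the models, numerical choices and known limitations of
specbind, in the spirit of a package-level methods section.

## Data model and units

All concentrations are mol/L internally; CSV headers declare the input
unit (`# unit=uM` by default, matching how binding constants are usually
reported in M⁻¹). F0, the free-protein fluorescence, is always the
measured zero-ligand point of a titration, never a fitted parameter: it is
the physical reference of every quenching quantity, and fitting it would
let baseline error masquerade as binding signal. Containers validate
physical invariants (positive intensities, strictly increasing ligand
grids, a mandatory zero-ligand row) at construction, so analysis code can
assume well-formed input.

## Inner-filter correction

F_corr = F_obs · 10^((a·A_ex + b·A_em)/10). The default factors (a, b) =
(5, 1) encode a 2 mm × 10 mm cuvette with absorbances measured over a
10 mm path: the short excitation path attenuates five-fold less per unit
absorbance read on the long path. Other geometries can supply their own
factors via `AnalysisConfig`. Correction is guarded against double
application, and points lacking absorbances pass through with a warning
rather than silently biasing the series.

## Stern–Volmer and mechanism classification

K_SV comes from OLS of F0/F on [Q]; with the unquenched lifetime τ0
supplied, k_q = K_SV/τ0. The mechanism verdict combines three criteria:

1. **Temperature trend** — K_SV strictly decreasing with T, with each step
   exceeding the sum of the two standard errors. With only ~3 temperatures
   a regression slope would be fragile; a significance-guarded
   monotonicity test is more honest.
2. **Lifetime criterion** — all |τ0/τ − 1| ≤ 0.1 while max F0/F − 1 > 0.1.
   The 0.1 tolerance operationalises "ratios close to unity"; it is
   configurable.
3. **Rate criterion** — all k_q above the diffusion limit, 10¹⁰ M⁻¹s⁻¹ by
   default.

"Static" requires at least two supporting criteria and no contradiction
(mirrored for "dynamic"); anything else is "ambiguous". The verdict is
invariant under reordering of the inputs.

## Double-log binding model

log₁₀((F0−F)/F) is regressed on log₁₀([Q]_free) with
[Q]_free = [Q]_tot − ((F0−F)/F0)·[P]_tot, the ligand-depletion estimate
that takes the bound fraction proportional to the quenched fraction. The
slope is the apparent stoichiometry n; K_a = 10^(intercept/n), with its
standard error by first-order propagation of the joint (slope, intercept)
uncertainty. Base-10 logarithms are used; K_a itself is base-independent
because slope and intercept enter jointly. Points with F ≥ F0 or
non-positive depleted concentration are excluded (the latter with a
warning).

## Van't Hoff thermodynamics

ln K_a on 1/T by unweighted OLS (optional 1/se² weighting): slope =
−ΔH/R, intercept = ΔS/R, R = 8.314 J·mol⁻¹·K⁻¹. ΔG(T) = ΔH − TΔS is
evaluated at each input temperature with errors from the full regression
covariance, var(ΔG) = R²(var_s + T²·var_i + 2T·cov_si). The covariance is
computed from the normal equations directly because numpy's `polyfit`
covariance is undefined at exactly three points. The driving-force label
follows the conventional sign rules (ΔH<0, ΔS<0 → van der Waals/hydrogen
bonding; both >0 → hydrophobic; ΔH<0, ΔS>0 → mixed), and a "balanced"
annotation is added when |ΔH| and |TΔS| at the median temperature agree
within 20% — the regime where neither term can be called dominant. The
model assumes a linear Van't Hoff plot, i.e. temperature-independent ΔH
(no ΔCp term).

## IDF / Scatchard / Hill

**ΔF curves.** ΔF = |F−F0|/F0 per point; ΔF(log₁₀[L]) is fitted with a
four-parameter logistic (the zero-ligand point anchors the curve but is
excluded from the log-axis fit). A monotone PCHIP interpolant is available
via `method="pchip"`; it reproduces noise-free data exactly and is what
the zero-noise recovery tests use, because the logistic family is only an
approximation to the true depletion-coupled isotherm shape (its
approximation bias on the recovered site number can reach ~10%). For noisy
data the logistic's smoothing is indispensable and it remains the default.

**Inversion.** At each quenching level the two fitted curves are inverted
for total ligand, and mass conservation at the two protein concentrations
gives Σν = ([L]₂−[L]₁)/([P]₂−[P]₁) and [L]_free = [L]₁ − Σν[P]₁. Twenty
levels are spread over the ΔF range common to both curves, excluding 5%
tails where inversion is ill-conditioned. Points with negative Σν or
[L]_free are flagged unusable and excluded downstream. The construction is
symmetric in the two curves.

**Scatchard.** (Σν, Σν/[L]_free) with a least-squares parabola as the
concavity diagnostic: concave-down (negative quadratic coefficient beyond
5% of the y-scale across the x-span) is evidence of positive
cooperativity; a classical non-cooperative isotherm gives a line.

**Hill fit.** Σν = n(K_b x)^h/(1+(K_b x)^h) by multistart least squares in
log-parameter space (positivity and ridge conditioning for free). K_b is
bounded to the identifiable window [10⁻²/x_max, 10²/x_min]: a
half-saturation point more than ~two decades outside the observed
free-ligand range is indistinguishable from a power law and produces
scientifically meaningless boundary solutions. A saturation warning is
raised when max Σν < 0.5·n with large n uncertainty.

**Uncertainty propagation.** The covariance of a Hill fit *conditional on
the inverted points* badly understates the real uncertainty, because all
inverted points derive from the same eight sigmoid parameters and their
errors are strongly correlated: in a 12-seed simulation study at 2%
intensity noise, naive 3-se intervals covered the truth in only 2/12
replicates. `idf_hill_analysis` therefore propagates the two sigmoid-fit
covariances through the whole inversion-and-fit chain by the delta method
(central finite differences of the fitted log-parameters along each
sigmoid parameter) and adds this to the fit covariance; coverage in the
same study rose to 12/12. The pipeline and the acceptance script use this
propagated uncertainty.

**Noise amplification — a real limitation.** The IDF difference signal is
the horizontal offset between two sigmoids, ~Σν·Δ[P]; with protein at 6
and 8 μM this is ~1–2 μM against total ligand of ~10–24 μM. At 2%
multiplicative intensity noise the offset is comparable to the sigmoid-fit
uncertainty, so point estimates of (n, K_b, h) scatter widely between
replicates even though the propagated intervals remain calibrated and the
Scatchard concavity diagnostic stays reliable. Percent-level intensity
precision (heavy accumulation averaging) is required before the chain pins
the Hill parameters tightly; synthetic-recovery tests at ≤0.5% noise
recover them to ~10%.

## Lifetime fitting

Tail fits from the histogram maximum onward: I(t) = ΣA_i·e^(−t/τ_i) + bg,
least squares with Poisson weights √max(counts, 1), amplitudes normalised
to fractions α_i afterwards. The absolute time axis is kept (a shifted
origin would bias the amplitude fractions by e^(t₀/τ_i)). No
instrument-response deconvolution: nanosecond lifetimes measured with a
pulsed-LED source are tail-fittable, and IRF support is out of scope. The
component count is a user choice (default 2); nearly degenerate lifetime
pairs (ratio < 1.2) trigger a warning rather than silent acceptance.
τ_avg = Σα_iτ_i²/Σα_iτ_i, the intensity-weighted mean.

## CD melting

Two-state sigmoid θ(T) = θ_nat + (θ_den−θ_nat)/(1+e^((Tm−T)/w)) with flat
baselines (no sloped-baseline treatment in v1). A transition is deemed
detectable when the amplitude exceeds 8× the point-noise scale estimated
from first differences — pure noise ranges stay below that over ~10²
samples. Baseline temperatures for the folded fraction default to the scan
extremes. Tm is reported with its fit standard error; by construction it
equals the temperature where the fitted folded fraction is 0.5.

## Synthetic data

The generators are the exact forward models of the estimators, so each
(simulator, estimator) pair is an inverse pair at zero noise. Defaults are
the study conditions of the HSP70-NBD/piperlongumine system: n = 2.2
sites, K_b = 6.3×10⁴ M⁻¹, h = 1.4 at 293 K; ΔH = −11.9 kJ/mol, ΔS =
+42.4 J/mol/K scaling constants across temperature; biexponential decay
(α = 0.6/0.4, τ = 0.8/3.0 ns); melt at Tm = 314 K with width 2.5 K and
baselines −20/−4 mdeg at 222 nm; 2% multiplicative intensity noise and 1%
melt noise; ligand extinction 18700 M⁻¹cm⁻¹ for inner-filter simulation.
Static quenching is modelled as F = F0(1 − q·Σν/n) with per-site quench
q = 0.9 — fractional-occupancy quenching, which makes ΔF sigmoidal in
log ligand as observed; the microscopic quench law of the real system is
unknown and this is an explicit modelling assumption. Free ligand under
mass conservation is solved by Brent root finding on the strictly monotone
residual x + ν(x)[P] − [L] (rtol 10⁻¹⁰); damped fixed-point iteration was
rejected because it diverges for h < 1 where the isotherm slope is
infinite at the origin. What the generator does **not** emulate: spectral
band shapes (peak intensities only), instrument response functions,
baseline drift, photobleaching, and correlated noise — so passing recovery
tests demonstrate estimator correctness, not robustness to every real-data
artefact.

## Problem sizes and tolerances

Recovery tests use the study design (25-point titrations, two protein
concentrations; 61-point melts; 256–512-bin decays at 10⁵–10⁶ counts,
10⁹ for zero-noise inverse-pair checks where integer rounding must sit
well below the 10⁻⁶ recovery tolerance). The noise-free end-to-end IDF
test uses a 0.25 μM grid with PCHIP inversion, isolating chain exactness
from interpolation density. Optimizer tolerances are 10⁻¹⁵ (log-space
least squares) and fits are multistarted from coarse grids over the
physically plausible region; ties resolve to the lowest residual.
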