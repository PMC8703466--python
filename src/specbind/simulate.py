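"""Forward simulators with known ground truth for every analysis stage.

Each simulator is the exact forward model of one estimator in the package,
so that (simulator, estimator) form an inverse pair at zero noise and the
whole pipeline can be verified by parameter recovery.

The titration simulator models cooperative n-site binding (Hill isotherm)
solved self-consistently with ligand mass conservation; static quenching
reduces the intensity in proportion to fractional site occupancy,
F = F0 (1 - q * nu / n), while dynamic quenching follows the Stern-Volmer
law directly.  Binding constants vary with temperature according to the
Van't Hoff relation.  TCSPC decays are multiexponential with Poisson
counting noise; CD melts are two-state sigmoids with Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import (
    CDMeltSeries,
    DecayCurve,
    TitrationPoint,
    TitrationSeries,
    ValidationError,
)
from .thermodynamics import R_GAS

__all__ = [
    "GroundTruth",
    "simulate_titration",
    "simulate_binding_equilibrium",
    "simulate_ka_series",
    "simulate_decay",
    "simulate_melt",
    "hill_binding_density",
    "solve_free_ligand",
]


@dataclass
class GroundTruth:
    """Generating parameters for the synthetic experiments.

    Defaults reproduce the study conditions of a small-molecule ligand
    binding the HSP70 nucleotide-binding domain: 2.2 cooperative sites with
    K_b = 6.3e4 M^-1 and Hill coefficient 1.4 at 293 K, static quenching,
    exothermic binding (dH = -11.9 kJ/mol, dS = +42.4 J/mol/K), a ~2 ns
    biexponential tryptophan decay, and a two-state melt at Tm = 314 K.
    """

    # binding (Hill isotherm, referenced to T_ref)
    n_sites: float = 2.2
    K_b: float = 6.3e4            # M^-1
    h: float = 1.4
    # 1:1 binding-equilibrium (double-log) reference constant
    K_a: float = 2.2e4            # M^-1
    n_stoich: float = 1.0
    # quenching
    quench_per_site: float = 0.9  # fractional quench at full occupancy
    mechanism: str = "static"     # "static" | "dynamic"
    K_SV: float = 1.5e4           # M^-1, dynamic-mode Stern-Volmer constant
    F0: float = 1000.0
    # thermodynamics (Van't Hoff)
    dH: float = -11.9             # kJ/mol
    dS: float = 42.4              # J/mol/K
    T_ref: float = 293.0          # K, temperature of the reference constants
    # inner-filter (ligand extinction, 1 cm absorbance path)
    epsilon_ex: float = 18700.0   # M^-1 cm^-1 at the excitation band
    epsilon_em: float = 1000.0    # M^-1 cm^-1 at the emission band
    # lifetimes (alpha_i, tau_i ns)
    lifetime_components: tuple[tuple[float, float], ...] = ((0.6, 0.8), (0.4, 3.0))
    # CD melt
    Tm: float = 314.0             # K
    melt_width: float = 2.5       # K
    theta_nat: float = -20.0      # mdeg at the native baseline (222 nm)
    theta_den: float = -4.0       # mdeg at the denatured baseline
    cd_protein_conc: float = 5e-6  # mol/L
    cd_path_cm: float = 0.01
    cd_n_residues: int = 383
    # noise
    noise_rel_intensity: float = 0.02
    noise_rel_melt: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sites, self.K_b, self.h, self.F0, self.K_a) <= 0:
            raise ValidationError("binding parameters must be positive")
        if not 0 <= self.quench_per_site <= 1:
            raise ValidationError("quench_per_site must be in [0, 1]")
        if self.mechanism not in ("static", "dynamic"):
            raise ValidationError("mechanism must be 'static' or 'dynamic'")

    def rng(self, seed: int | None = None) -> np.random.Generator:
        return np.random.default_rng(self.seed if seed is None else seed)

    def k_at(self, K_ref: float, T: float) -> float:
        """Van't Hoff temperature scaling of a reference binding constant."""
        return K_ref * np.exp(-self.dH * 1000.0 / R_GAS * (1.0 / T - 1.0 / self.T_ref))


def hill_binding_density(x_free, n: float, kb: float, h: float):
    """Average ligands bound per protein at free ligand concentration x."""
    z = (kb * np.asarray(x_free, dtype=float)) ** h
    return n * z / (1.0 + z)


def solve_free_ligand(
    ligand_total: float,
    protein_total: float,
    n: float,
    kb: float,
    h: float,
    *,
    tol: float = 1e-10,
) -> float:
    """Self-consistent free-ligand concentration under mass conservation.

    Solves x + nu(x) P = L by bracketed root finding; f is strictly
    increasing in x with f(0) < 0 <= f(L), so a root always exists and
    Brent's method converges for any Hill exponent (including h < 1, where
    the isotherm slope diverges at x -> 0 and fixed-point schemes fail).
    """
    if ligand_total == 0:
        return 0.0

    def f(x: float) -> float:
        return x + float(hill_binding_density(x, n, kb, h)) * protein_total - ligand_total

    from scipy.optimize import brentq

    try:
        return float(
            brentq(f, 1e-300, ligand_total, xtol=1e-300, rtol=tol, maxiter=500)
        )
    except (RuntimeError, ValueError) as err:
        raise ValidationError(
            f"mass-conservation solve failed at L={ligand_total:g}: {err}"
        ) from err


def simulate_titration(
    truth: GroundTruth,
    protein_total: float,
    ligand_grid,
    temperature: float = 293.0,
    *,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    inner_filter: bool = False,
) -> TitrationSeries:
    """Simulate a fluorescence titration at one protein concentration.

    The ligand grid must start at 0 (the F0 point).  With
    ``inner_filter=True`` the observed intensities are attenuated by the
    ligand's absorbance (A = epsilon * [L]_tot over a 1 cm path) and the
    absorbances are attached to each point, so the inner-filter correction
    can be exercised; the series is then flagged uncorrected.
    """
    grid = np.asarray(ligand_grid, dtype=float)
    if grid[0] != 0:
        raise ValidationError("ligand grid must start at 0")
    rng = truth.rng() if rng is None else rng
    kb_T = truth.k_at(truth.K_b, temperature)
    points = []
    for L in grid:
        if truth.mechanism == "static":
            x = solve_free_ligand(L, protein_total, truth.n_sites, kb_T, truth.h)
            nu = float(hill_binding_density(x, truth.n_sites, kb_T, truth.h))
            F = truth.F0 * (1.0 - truth.quench_per_site * nu / truth.n_sites)
        else:
            ksv_T = truth.k_at(truth.K_SV, temperature)
            F = truth.F0 / (1.0 + ksv_T * L)
        if noise and truth.noise_rel_intensity > 0:
            F *= 1.0 + truth.noise_rel_intensity * rng.standard_normal()
            F = max(F, truth.F0 * 1e-6)
        A_ex = A_em = None
        if inner_filter:
            A_ex = truth.epsilon_ex * L
            A_em = truth.epsilon_em * L
            F *= 10.0 ** (-(5.0 * A_ex + A_em) / 10.0)
        points.append(TitrationPoint(float(L), float(F), A_ex, A_em))
    return TitrationSeries(
        protein_total=protein_total,
        temperature=temperature,
        points=tuple(points),
        corrected=not inner_filter,
        label=f"sim P={protein_total:g} T={temperature:g}",
    )


def simulate_binding_equilibrium(
    truth: GroundTruth,
    protein_total: float,
    free_ligand_grid,
    temperature: float = 293.0,
    *,
    rng: np.random.Generator | None = None,
    noise: bool = False,
) -> TitrationSeries:
    """Simulate a titration obeying the double-log binding-equilibrium model.

    Generated from (F0-F)/F = (K_a x)^n over a grid of FREE ligand
    concentrations; the total ligand of each point is reconstructed from
    the ligand-depletion relation [L]_tot = x + ((F0-F)/F0) [P]_tot, so the
    double-log estimator is the exact inverse of this simulator.
    """
    rng = truth.rng() if rng is None else rng
    ka_T = truth.k_at(truth.K_a, temperature)
    pts = [TitrationPoint(0.0, truth.F0)]
    for x in np.asarray(free_ligand_grid, dtype=float):
        if x <= 0:
            continue
        r = (ka_T * x) ** truth.n_stoich
        F = truth.F0 / (1.0 + r)
        dF = r / (1.0 + r)
        L = x + dF * protein_total
        if noise and truth.noise_rel_intensity > 0:
            F *= 1.0 + truth.noise_rel_intensity * rng.standard_normal()
        pts.append(TitrationPoint(float(L), float(F)))
    return TitrationSeries(
        protein_total=protein_total,
        temperature=temperature,
        points=tuple(pts),
        corrected=True,
        label=f"sim-dlog P={protein_total:g} T={temperature:g}",
    )


def simulate_ka_series(truth: GroundTruth, temperatures) -> dict[float, float]:
    """Binding constants on an exact Van't Hoff line: K(T) = exp(-dH/RT + dS/R)."""
    out = {}
    for T in temperatures:
        if T <= 0:
            raise ValidationError("temperatures must be > 0")
        out[float(T)] = float(
            np.exp(-truth.dH * 1000.0 / (R_GAS * T) + truth.dS / R_GAS)
        )
    return out


def simulate_decay(
    truth: GroundTruth,
    n_photons: float = 1e6,
    bin_width_ns: float = 0.05,
    n_bins: int = 512,
    *,
    ligand_total: float = 0.0,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    background_fraction: float = 0.0,
) -> DecayCurve:
    """Simulate a TCSPC histogram from the truth's multiexponential decay.

    Under static quenching the lifetimes are ligand-independent; under
    dynamic quenching each component is shortened,
    tau(L) = tau0 / (1 + K_SV L).  Expected counts are normalised to
    ``n_photons`` and drawn Poisson (or rounded when ``noise=False``).
    """
    rng = truth.rng() if rng is None else rng
    t = (np.arange(n_bins) + 0.5) * bin_width_ns
    comps = truth.lifetime_components
    if truth.mechanism == "dynamic" and ligand_total > 0:
        factor = 1.0 + truth.K_SV * ligand_total
        comps = tuple((a, tau / factor) for a, tau in comps)
    expected = np.zeros_like(t)
    for a, tau in comps:
        expected += a * np.exp(-t / tau)
    expected *= n_photons * (1.0 - background_fraction) / expected.sum()
    expected += n_photons * background_fraction / n_bins
    counts = rng.poisson(expected) if noise else np.round(expected).astype(np.int64)
    return DecayCurve(
        time_bins=tuple(t), counts=tuple(int(c) for c in counts),
        ligand_total=ligand_total,
    )


def simulate_melt(
    truth: GroundTruth,
    temperature_grid=None,
    *,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> CDMeltSeries:
    """Simulate a two-state CD melting scan (default 280-340 K, 1 K steps).

    Gaussian noise has standard deviation ``noise_rel_melt`` times the
    baseline separation.
    """
    rng = truth.rng() if rng is None else rng
    T = (
        np.arange(280.0, 340.0 + 1e-9, 1.0)
        if temperature_grid is None
        else np.asarray(temperature_grid, dtype=float)
    )
    theta = truth.theta_nat + (truth.theta_den - truth.theta_nat) / (
        1.0 + np.exp((truth.Tm - T) / truth.melt_width)
    )
    if noise and truth.noise_rel_melt > 0:
        theta = theta + truth.noise_rel_melt * abs(
            truth.theta_den - truth.theta_nat
        ) * rng.standard_normal(len(T))
    return CDMeltSeries(
        temperature_K=tuple(T),
        theta_mdeg=tuple(theta),
        monitor_wavelength=222.0,
        protein_conc=truth.cd_protein_conc,
        path_cm=truth.cd_path_cm,
        n_residues=truth.cd_n_residues,
    )
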