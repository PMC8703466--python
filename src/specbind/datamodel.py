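"""Domain containers for spectroscopic binding experiments.

All concentrations are stored in mol/L internally; file readers convert
from the unit declared in the file header.  Containers validate their
physical invariants on construction, so any instance reaching an analysis
routine is already well-formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "TitrationPoint",
    "TitrationSeries",
    "DecayCurve",
    "CDSpectrumPoint",
    "CDMeltSeries",
    "AnalysisConfig",
    "ValidationError",
    "UNIT_FACTORS",
]

#: multiplicative factors converting a declared concentration unit to mol/L
UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
}


class ValidationError(ValueError):
    """Raised when experimental data violates a physical invariant."""


@dataclass(frozen=True)
class TitrationPoint:
    """One point of a fluorescence titration.

    Parameters
    ----------
    ligand_total : float
        Total quencher/ligand concentration in mol/L.
    F_obs : float
        Fluorescence intensity (arbitrary units, > 0).
    A_ex, A_em : float, optional
        Absorbance of the sample at the excitation and emission
        wavelengths, used for inner-filter correction.
    """

    ligand_total: float
    F_obs: float
    A_ex: float | None = None
    A_em: float | None = None

    def __post_init__(self) -> None:
        if self.ligand_total < 0:
            raise ValidationError(f"ligand_total must be >= 0, got {self.ligand_total}")
        if self.F_obs <= 0:
            raise ValidationError(f"F_obs must be > 0, got {self.F_obs}")
        for name in ("A_ex", "A_em"):
            a = getattr(self, name)
            if a is not None and a < 0:
                raise ValidationError(f"{name} must be >= 0, got {a}")


@dataclass(frozen=True)
class TitrationSeries:
    """Fluorescence intensity vs total ligand at fixed protein and temperature.

    The first point must have ``ligand_total == 0``; its intensity defines
    F0, the free-protein signal.
    """

    protein_total: float
    temperature: float
    points: tuple[TitrationPoint, ...]
    corrected: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if self.protein_total <= 0:
            raise ValidationError(f"protein_total must be > 0, got {self.protein_total}")
        if self.temperature <= 0:
            raise ValidationError(f"temperature must be > 0, got {self.temperature}")
        if not self.points:
            raise ValidationError("series has no points")
        if self.points[0].ligand_total != 0:
            raise ValidationError(
                f"series {self.label or self._key()}: first point must have "
                f"ligand_total = 0 (defines F0), got {self.points[0].ligand_total}"
            )
        lig = [p.ligand_total for p in self.points]
        if any(b <= a for a, b in zip(lig, lig[1:])):
            raise ValidationError(
                f"series {self.label or self._key()}: ligand_total must be "
                "strictly increasing"
            )

    def _key(self) -> str:
        return f"(P={self.protein_total:g} M, T={self.temperature:g} K)"

    @property
    def F0(self) -> float:
        """Free-protein fluorescence (zero-ligand point)."""
        return self.points[0].F_obs

    @property
    def ligand(self) -> list[float]:
        return [p.ligand_total for p in self.points]

    @property
    def intensity(self) -> list[float]:
        return [p.F_obs for p in self.points]

    def with_points(self, points: Sequence[TitrationPoint], *, corrected: bool | None = None):
        return replace(
            self,
            points=tuple(points),
            corrected=self.corrected if corrected is None else corrected,
        )


@dataclass(frozen=True)
class DecayCurve:
    """TCSPC decay histogram: photon counts per uniform time bin (ns)."""

    time_bins: tuple[float, ...]
    counts: tuple[int, ...]
    ligand_total: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_bins", tuple(float(t) for t in self.time_bins))
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if len(self.time_bins) != len(self.counts):
            raise ValidationError("time_bins and counts must have equal length")
        t = self.time_bins
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError("time bins must be strictly increasing")
        if any(c < 0 for c in self.counts):
            raise ValidationError("counts must be non-negative")
        if self.ligand_total < 0:
            raise ValidationError("ligand_total must be >= 0")

    @property
    def total_counts(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class CDSpectrumPoint:
    """Ellipticity (millidegrees) at one wavelength (nm)."""

    wavelength: float
    theta_mdeg: float


@dataclass(frozen=True)
class CDMeltSeries:
    """Ellipticity at a monitored wavelength as a function of temperature.

    ``protein_conc`` (mol/L), ``path_cm`` and ``n_residues`` are the inputs
    of the mean-residue-ellipticity conversion.
    """

    temperature_K: tuple[float, ...]
    theta_mdeg: tuple[float, ...]
    monitor_wavelength: float
    protein_conc: float
    path_cm: float
    n_residues: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperature_K", tuple(float(t) for t in self.temperature_K))
        object.__setattr__(self, "theta_mdeg", tuple(float(x) for x in self.theta_mdeg))
        if len(self.temperature_K) != len(self.theta_mdeg):
            raise ValidationError("temperature and ellipticity arrays must match")
        t = self.temperature_K
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError("temperatures must be strictly increasing")
        if self.protein_conc <= 0:
            raise ValidationError("protein_conc must be > 0")
        if self.path_cm <= 0:
            raise ValidationError("path_cm must be > 0")
        if self.n_residues < 1:
            raise ValidationError("n_residues must be >= 1")


@dataclass
class AnalysisConfig:
    """Run-wide configuration.

    Attributes
    ----------
    concentration_unit : str
        Unit of concentrations in input files (overridden by a file header).
    ifc_a, ifc_b : float
        Path-length factors of the inner-filter correction
        ``F_corr = F_obs * 10**((a*A_ex + b*A_em)/10)``; the defaults (5, 1)
        encode a 2 mm x 10 mm cuvette with absorbances measured over 10 mm.
    log_base : float
        Base of the logarithms in the double-log and binding-density axes.
    tau_ratio_tol : float
        Tolerance on |tau0/tau - 1| for the lifetime mechanism criterion.
    diffusion_limit : float
        Upper bound (M^-1 s^-1) of a diffusion-controlled bimolecular rate.
    seed : int
        Seed for any stochastic step.
    """

    concentration_unit: str = "uM"
    ifc_a: float = 5.0
    ifc_b: float = 1.0
    log_base: float = 10.0
    tau_ratio_tol: float = 0.1
    diffusion_limit: float = 1e10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ifc_a <= 0 or self.ifc_b <= 0:
            raise ValidationError("inner-filter path factors must be > 0")
        if self.log_base <= 1:
            raise ValidationError("log_base must be > 1")
        if self.concentration_unit not in UNIT_FACTORS:
            raise ValidationError(
                f"unknown concentration unit {self.concentration_unit!r}; "
                f"known: {sorted(UNIT_FACTORS)}"
            )
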