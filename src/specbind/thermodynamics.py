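"""Van't Hoff thermodynamic decomposition of binding constants.

Linear regression of ln K_a against 1/T,

    ln K_a = -dH/(R T) + dS/R,

yields the binding enthalpy dH (from the slope) and entropy dS (from the
intercept); the Gibbs energy follows as dG = dH - T dS.  The sign pattern
of (dH, dS) classifies the dominant intermolecular force: both negative
points to van der Waals contacts / hydrogen bonding, both positive to
hydrophobic (entropy-driven) burial, and dH < 0 with dS > 0 to a mixture of
electrostatic and van der Waals contributions.  When |dH| and |T dS| are of
near-equal magnitude the binding is additionally flagged as
enthalpy-entropy balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ValidationError
from .io import register_result

__all__ = [
    "R_GAS",
    "ThermoResult",
    "VantHoff",
    "vant_hoff_fit",
    "gibbs",
    "classify_driving_force",
]

#: molar gas constant, J mol^-1 K^-1
R_GAS = 8.314


def gibbs(dH_kJ: float, dS_J: float, T: float) -> float:
    """Gibbs energy dG = dH - T dS in kJ/mol (dH in kJ/mol, dS in J/mol/K)."""
    if T <= 0:
        raise ValidationError("temperature must be > 0")
    return dH_kJ - T * dS_J / 1000.0


def classify_driving_force(
    dH_kJ: float, dS_J: float, T: float = 298.15, balance_tol: float = 0.2
) -> str:
    """Label the dominant interaction from the signs of dH and dS.

    Appends ", enthalpy-entropy balanced" when |dH| and |T dS| agree within
    ``balance_tol`` relative difference.
    """
    if dH_kJ < 0 and dS_J < 0:
        label = "van der Waals / hydrogen bonding"
    elif dH_kJ > 0 and dS_J > 0:
        label = "hydrophobic"
    elif dH_kJ < 0 and dS_J > 0:
        label = "mixed (electrostatic or van der Waals)"
    else:
        label = "unfavorable (dH > 0, dS < 0)"
    tds = abs(T * dS_J / 1000.0)
    scale = max(abs(dH_kJ), tds)
    if scale > 0 and abs(abs(dH_kJ) - tds) / scale <= balance_tol:
        label += ", enthalpy-entropy balanced"
    return label


@register_result
@dataclass(frozen=True)
class ThermoResult:
    """Van't Hoff estimates: dH (kJ/mol), dS (J/mol/K), dG and T dS per T."""

    dH: float
    dH_se: float
    dS: float
    dS_se: float
    dG_at: dict[float, float]
    dG_se_at: dict[float, float]
    TdS_at: dict[float, float]
    driving_force_label: str
    r_squared: float

    def summary(self) -> str:
        lines = [
            "Van't Hoff analysis",
            f"  dH   {self.dH:8.2f} +/- {self.dH_se:.2f} kJ/mol",
            f"  dS   {self.dS:8.2f} +/- {self.dS_se:.2f} J/mol/K",
            f"  R^2  {self.r_squared:8.5f}",
            f"  driving force: {self.driving_force_label}",
            "  T (K)    dG (kJ/mol)       T*dS (kJ/mol)",
        ]
        for T in sorted(self.dG_at):
            lines.append(
                f"  {T:6.1f}  {self.dG_at[T]:8.2f} +/- {self.dG_se_at[T]:.2f}"
                f"   {self.TdS_at[T]:8.2f}"
            )
        return "\n".join(lines)


class VantHoff:
    """Van't Hoff regression model over temperature-resolved K_a values.

    Parameters
    ----------
    ka_by_T : dict
        Map temperature (K) -> K_a (M^-1) or (K_a, se).  The optional
        standard errors enable 1/se^2 weighting via ``weighted=True``.
    allow_two_points : bool
        Permit an exact two-point solve; errors are then reported as NaN.
    """

    def __init__(
        self,
        ka_by_T: dict[float, float | tuple[float, float]],
        *,
        weighted: bool = False,
        allow_two_points: bool = False,
    ):
        items = sorted(ka_by_T.items())
        self.T = np.array([t for t, _ in items], dtype=float)
        vals = [v if isinstance(v, (tuple, list)) else (v, None) for _, v in items]
        self.Ka = np.array([v[0] for v in vals], dtype=float)
        self.Ka_se = np.array(
            [np.nan if v[1] is None else v[1] for v in vals], dtype=float
        )
        if np.any(self.Ka <= 0):
            raise ValidationError("all K_a must be > 0")
        if np.any(self.T <= 0):
            raise ValidationError("all temperatures must be > 0")
        n = len(self.T)
        if n < 2 or (n == 2 and not allow_two_points):
            raise ValidationError(
                "Van't Hoff fit needs >= 3 temperatures "
                "(2 allowed with allow_two_points=True)"
            )
        if weighted and np.any(np.isnan(self.Ka_se)):
            raise ValidationError("weighted fit requires a standard error per K_a")
        self.weighted = weighted

    def fit(self, balance_tol: float = 0.2) -> ThermoResult:
        x = 1.0 / self.T
        y = np.log(self.Ka)
        if self.weighted:
            w = (self.Ka / self.Ka_se) ** 2  # var(ln K) = (se/K)^2
        else:
            w = None
        if len(x) == 2:
            slope = (y[1] - y[0]) / (x[1] - x[0])
            intercept = y[0] - slope * x[0]
            cov = np.full((2, 2), np.nan)
            r2 = 1.0
        else:
            X = np.column_stack([x, np.ones_like(x)])
            W = np.ones_like(x) if w is None else w
            XtWX = X.T @ (W[:, None] * X)
            beta = np.linalg.solve(XtWX, X.T @ (W * y))
            slope, intercept = beta
            yhat = X @ beta
            ss_res = float(np.sum(W * (y - yhat) ** 2))
            if self.weighted:
                cov = np.linalg.inv(XtWX)  # weights carry the error scale
            else:
                sigma2 = ss_res / (len(x) - 2)
                cov = sigma2 * np.linalg.inv(XtWX)
            ss_tot = float(np.sum(W * (y - np.average(y, weights=W)) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dH = -R_GAS * slope / 1000.0  # kJ/mol
        dS = R_GAS * intercept  # J/mol/K
        dH_se = R_GAS * np.sqrt(cov[0, 0]) / 1000.0
        dS_se = R_GAS * np.sqrt(cov[1, 1])
        dG_at, dG_se_at, TdS_at = {}, {}, {}
        for T in self.T:
            T = float(T)
            dG_at[T] = gibbs(dH, dS, T)
            # dG = -R(slope + T*intercept); propagate regression covariance
            var = R_GAS**2 * (cov[0, 0] + T**2 * cov[1, 1] + 2 * T * cov[0, 1])
            dG_se_at[T] = float(np.sqrt(var)) / 1000.0
            TdS_at[T] = T * dS / 1000.0
        label = classify_driving_force(
            dH, dS, T=float(np.median(self.T)), balance_tol=balance_tol
        )
        return ThermoResult(
            dH=float(dH),
            dH_se=float(dH_se),
            dS=float(dS),
            dS_se=float(dS_se),
            dG_at=dG_at,
            dG_se_at=dG_se_at,
            TdS_at=TdS_at,
            driving_force_label=label,
            r_squared=float(r2),
        )


def vant_hoff_fit(
    ka_by_T: dict[float, float | tuple[float, float]],
    *,
    weighted: bool = False,
    allow_two_points: bool = False,
) -> ThermoResult:
    """Functional wrapper around :class:`VantHoff`."""
    return VantHoff(
        ka_by_T, weighted=weighted, allow_two_points=allow_two_points
    ).fit()
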