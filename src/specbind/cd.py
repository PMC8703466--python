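"""Circular-dichroism melting analysis.

Ellipticity in millidegrees is converted to mean residue ellipticity,

    [theta] = theta_mdeg / (10 [P] l n)      (deg cm^2 dmol^-1),

with molar protein concentration [P], path length l (cm) and residue count
n.  A thermal unfolding scan monitored at a single wavelength is treated as
a two-state transition: the ellipticity follows the sigmoid

    theta(T) = theta_nat + (theta_den - theta_nat) / (1 + exp((Tm - T)/w)),

whose midpoint Tm is the melting temperature and w the transition width.
The folded fraction is the affine map between the native and denatured
baselines, f = (theta_obs - theta_den) / (theta_nat - theta_den).
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass

from scipy import optimize

from .datamodel import CDMeltSeries, ValidationError
from .io import register_result

__all__ = [
    "MeltResult",
    "MeltingModel",
    "mean_residue_ellipticity",
    "folded_fraction",
    "fit_melting",
]


def mean_residue_ellipticity(
    theta_mdeg: float, protein_conc: float, path_cm: float, n_residues: int
) -> float:
    """Convert millidegrees to mean residue ellipticity (deg cm^2 dmol^-1)."""
    if protein_conc <= 0 or path_cm <= 0 or n_residues < 1:
        raise ValidationError(
            "protein_conc and path_cm must be > 0 and n_residues >= 1"
        )
    return theta_mdeg / (10.0 * protein_conc * path_cm * n_residues)


def folded_fraction(
    series: CDMeltSeries, nat_T: float | None = None, den_T: float | None = None
) -> np.ndarray:
    """Folded fraction per temperature from native/denatured baselines.

    Baseline temperatures default to the scan extremes.  f(nat_T) = 1 and
    f(den_T) = 0 by construction; the transform is invariant under any
    affine rescaling of the ellipticity axis.
    """
    T = np.asarray(series.temperature_K)
    theta = np.asarray(series.theta_mdeg)
    nat_T = T[0] if nat_T is None else nat_T
    den_T = T[-1] if den_T is None else den_T
    for name, val in (("nat_T", nat_T), ("den_T", den_T)):
        if not (T[0] <= val <= T[-1]):
            raise ValidationError(f"{name}={val} outside the scanned range")
    th_nat = float(np.interp(nat_T, T, theta))
    th_den = float(np.interp(den_T, T, theta))
    if th_nat == th_den:
        raise ValidationError("native and denatured baselines are equal")
    return (theta - th_den) / (th_nat - th_den)


def _two_state(T, th_nat, th_den, Tm, w):
    return th_nat + (th_den - th_nat) / (1.0 + np.exp((Tm - T) / w))


@register_result
@dataclass(frozen=True)
class MeltResult:
    """Two-state melt fit: Tm (K), width, baselines, per-T folded fraction."""

    Tm: float
    Tm_se: float
    width: float
    width_se: float
    theta_nat: float
    theta_den: float
    fraction_folded: tuple[float, ...]
    temperature_K: tuple[float, ...]
    r_squared: float

    def summary(self) -> str:
        return "\n".join(
            [
                "Two-state melting fit",
                f"  Tm         {self.Tm:8.2f} +/- {self.Tm_se:.2f} K",
                f"  width      {self.width:8.2f} +/- {self.width_se:.2f} K",
                f"  theta_nat  {self.theta_nat:10.4g}",
                f"  theta_den  {self.theta_den:10.4g}",
                f"  R^2        {self.r_squared:10.6f}",
            ]
        )


class MeltingModel:
    """Two-state sigmoid fitted to an ellipticity-vs-temperature scan.

    Flat (temperature-independent) baselines; requires at least 8
    temperatures spanning both baselines and a transition amplitude
    distinguishable from noise.
    """

    def __init__(self, series: CDMeltSeries, *, min_points: int = 8):
        if len(series.temperature_K) < min_points:
            raise ValidationError(f"melting fit needs >= {min_points} temperatures")
        self.series = series

    def fit(self) -> MeltResult:
        T = np.asarray(self.series.temperature_K)
        theta = np.asarray(self.series.theta_mdeg)
        amp = theta.max() - theta.min()
        # point-noise scale from first differences; the range of pure noise
        # over ~10^2 samples stays below ~8 sigma
        sigma_est = float(np.std(np.diff(theta))) / np.sqrt(2)
        if amp == 0 or amp <= 8 * sigma_est:
            raise ValidationError(
                "no detectable transition: baseline separation within noise"
            )
        mid = 0.5 * (theta[0] + theta[-1])
        Tm0 = float(T[np.argmin(np.abs(theta - mid))])
        p0 = (float(theta[0]), float(theta[-1]), Tm0, (T[-1] - T[0]) / 20.0)
        bounds = (
            [-np.inf, -np.inf, T[0], 1e-3],
            [np.inf, np.inf, T[-1], (T[-1] - T[0])],
        )
        try:
            popt, pcov = optimize.curve_fit(
                _two_state, T, theta, p0=p0, bounds=bounds, maxfev=50000,
                xtol=1e-14, ftol=1e-14,
            )
        except RuntimeError as err:
            raise ValidationError(f"melting fit did not converge: {err}") from err
        th_nat, th_den, Tm, w = (float(v) for v in popt)
        se = np.sqrt(np.diag(pcov))
        frac = (_two_state(T, *popt) - th_den) / (th_nat - th_den)
        resid = theta - _two_state(T, *popt)
        ss_tot = float(np.sum((theta - theta.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        return MeltResult(
            Tm=Tm,
            Tm_se=float(se[2]),
            width=w,
            width_se=float(se[3]),
            theta_nat=th_nat,
            theta_den=th_den,
            fraction_folded=tuple(float(f) for f in frac),
            temperature_K=tuple(float(t) for t in T),
            r_squared=r2,
        )


def fit_melting(series: CDMeltSeries, **kwargs) -> MeltResult:
    """Functional wrapper around :class:`MeltingModel`."""
    return MeltingModel(series, **kwargs).fit()
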