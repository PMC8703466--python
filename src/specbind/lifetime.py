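"""TCSPC fluorescence-lifetime analysis.

Decay histograms are tail-fitted (from the histogram maximum onward, no
instrument-response deconvolution) with a sum of exponentials plus a
constant background,

    I(t) = sum_i A_i exp(-t / tau_i) + bg,

using Poisson-weighted least squares.  The intensity-weighted average
lifetime

    tau_avg = sum_i alpha_i tau_i^2 / sum_i alpha_i tau_i

feeds the tau0/tau criterion of the quenching-mechanism test: static
quenching leaves lifetimes unchanged (ratios ~ 1) while the steady-state
ratio F0/F rises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datamodel import AnalysisConfig, DecayCurve, ValidationError
from .io import register_result

__all__ = [
    "LifetimeResult",
    "DecayModel",
    "fit_decay",
    "average_lifetime",
    "lifetime_ratio_series",
]


def average_lifetime(components: list[tuple[float, float]]) -> float:
    """Intensity-weighted average lifetime from (alpha_i, tau_i) components.

    tau_avg = sum alpha tau^2 / sum alpha tau; invariant under rescaling of
    the amplitudes, and equal to sum f_i tau_i with intensity fractions
    f_i = alpha_i tau_i / sum alpha_j tau_j.
    """
    a = np.array([c[0] for c in components], dtype=float)
    t = np.array([c[1] for c in components], dtype=float)
    if np.any(t <= 0) or np.any(a < 0) or a.sum() == 0:
        raise ValidationError("components need tau > 0 and alpha >= 0, not all zero")
    return float(np.sum(a * t**2) / np.sum(a * t))


@register_result
@dataclass(frozen=True)
class LifetimeResult:
    """Multiexponential decay estimates: (alpha_i, tau_i ns), tau_avg, chi2."""

    components: tuple[tuple[float, float], ...]  # (alpha, tau) sorted by tau
    components_se: tuple[tuple[float, float], ...]
    tau_avg: float
    chi2_reduced: float
    background: float
    ligand_total: float

    def summary(self) -> str:
        lines = ["Lifetime fit"]
        for (a, t), (a_se, t_se) in zip(self.components, self.components_se):
            lines.append(
                f"  alpha {a:6.3f} +/- {a_se:.3f}   tau {t:7.3f} +/- {t_se:.3f} ns"
            )
        lines += [
            f"  tau_avg      {self.tau_avg:8.3f} ns",
            f"  chi2_reduced {self.chi2_reduced:8.3f}",
        ]
        return "\n".join(lines)


def _multi_exp(t, *params):
    # params: A_1, tau_1, ..., A_k, tau_k, bg  (amplitudes in counts)
    k = (len(params) - 1) // 2
    out = np.full_like(t, params[-1], dtype=float)
    for i in range(k):
        out += params[2 * i] * np.exp(-t / params[2 * i + 1])
    return out


class DecayModel:
    """Tail fit of a TCSPC histogram with 1-3 exponential components."""

    def __init__(
        self,
        curve: DecayCurve,
        n_components: int = 2,
        config: AnalysisConfig | None = None,
        *,
        counts_floor: int = 10_000,
    ):
        if not 1 <= n_components <= 3:
            raise ValidationError("n_components must be 1, 2 or 3")
        if curve.total_counts < counts_floor:
            raise ValidationError(
                f"total counts {curve.total_counts} below floor {counts_floor}"
            )
        self.curve = curve
        self.k = n_components

    def fit(self) -> LifetimeResult:
        t_all = np.asarray(self.curve.time_bins)
        c_all = np.asarray(self.curve.counts, dtype=float)
        peak = int(np.argmax(c_all))
        # tail region from the histogram maximum; absolute time axis so the
        # fitted amplitudes refer to t = 0 (a shifted origin would bias the
        # per-component amplitude fractions by exp(t0/tau_i))
        t = t_all[peak:]
        c = c_all[peak:]
        span = t[-1] - t[0] if t[-1] > t[0] else 1.0
        peak_counts = c.max()
        p0 = []
        for i in range(self.k):
            p0 += [peak_counts / self.k, span * 0.1 * (i + 1)]
        p0.append(max(c.min(), 1.0))
        lb = [0.0, 1e-6] * self.k + [0.0]
        ub = [np.inf, span * 100] * self.k + [np.inf]
        sigma = np.sqrt(np.maximum(c, 1.0))  # Poisson weighting
        try:
            popt, pcov = optimize.curve_fit(
                _multi_exp, t, c, p0=p0, sigma=sigma, absolute_sigma=True,
                bounds=(lb, ub), maxfev=100000,
            )
        except RuntimeError as err:
            raise ValidationError(f"decay fit did not converge: {err}") from err
        resid = (c - _multi_exp(t, *popt)) / sigma
        dof = max(len(t) - len(popt), 1)
        chi2 = float(np.sum(resid**2) / dof)
        amps = popt[0 : 2 * self.k : 2]
        taus = popt[1 : 2 * self.k : 2]
        se = np.sqrt(np.diag(pcov))
        amp_se = se[0 : 2 * self.k : 2]
        tau_se = se[1 : 2 * self.k : 2]
        total = amps.sum()
        alphas = amps / total
        alpha_se = amp_se / total
        order = np.argsort(taus)
        comps = tuple((float(alphas[i]), float(taus[i])) for i in order)
        comps_se = tuple((float(alpha_se[i]), float(tau_se[i])) for i in order)
        taus_sorted = [c_[1] for c_ in comps]
        for a, b in zip(taus_sorted, taus_sorted[1:]):
            if b / a < 1.2:
                warnings.warn(
                    f"lifetime components {a:.3g} and {b:.3g} ns are nearly "
                    "degenerate (ratio < 1.2); consider fewer components",
                    stacklevel=2,
                )
        return LifetimeResult(
            components=comps,
            components_se=comps_se,
            tau_avg=average_lifetime(comps),
            chi2_reduced=chi2,
            background=float(popt[-1]),
            ligand_total=self.curve.ligand_total,
        )


def fit_decay(
    curve: DecayCurve,
    n_components: int = 2,
    config: AnalysisConfig | None = None,
    **kwargs,
) -> LifetimeResult:
    """Functional wrapper around :class:`DecayModel`."""
    return DecayModel(curve, n_components, config, **kwargs).fit()


def lifetime_ratio_series(
    results: list[LifetimeResult],
) -> list[tuple[float, float]]:
    """(ligand_total, tau0/tau) per concentration, tau0 from the zero-ligand entry."""
    zero = [r for r in results if r.ligand_total == 0]
    if not zero:
        raise ValidationError("no zero-ligand lifetime result; tau0 undefined")
    tau0 = zero[0].tau_avg
    return [
        (r.ligand_total, tau0 / r.tau_avg)
        for r in sorted(results, key=lambda r: r.ligand_total)
    ]
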