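"""Model-free Interaction Density Function (IDF) binding analysis.

The IDF method extracts the binding isotherm from fluorescence quenching
without assuming a binding model.  Its premise: if two titrations at
different total protein concentrations show the same fractional quenching
dF = |F - F0|/F0, the free ligand concentration and the average binding
density (ligands bound per protein, sum nu) are the same in both.  Mass
conservation,

    [L]_tot = [L]_free + (sum nu) [P]_tot,

written at the two protein concentrations then gives a 2x2 linear system
per quenching level:

    sum nu   = ([L]_2 - [L]_1) / ([P]_2 - [P]_1)
    [L]_free = [L]_1 - (sum nu) [P]_1.

The resulting (free ligand, binding density) points are examined by a
Scatchard transformation (nu/x vs nu; concave-down indicates positive
cooperativity) and fitted with the Hill model

    sum nu = n (K_b x)^h / (1 + (K_b x)^h)

for the site number n, binding constant K_b and Hill coefficient h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.interpolate import PchipInterpolator

from .datamodel import TitrationSeries, ValidationError
from .io import register_result

__all__ = [
    "QuenchCurve",
    "IDFPoint",
    "ScatchardResult",
    "HillResult",
    "HillModel",
    "delta_f",
    "idf_invert",
    "scatchard",
    "hill_fit",
]


def _logistic4(u, lo, hi, c, s):
    return lo + (hi - lo) / (1.0 + 10.0 ** (s * (c - u)))


@dataclass
class QuenchCurve:
    """Fractional quenching dF vs log10 total ligand with a fitted sigmoid.

    ``params`` holds the four-parameter logistic (lo, hi, c, s) in
    u = log10([L]_tot); ``method`` may instead select a monotone PCHIP
    interpolant ("pchip") used verbatim for inversion.
    """

    series: TitrationSeries
    dF: np.ndarray
    params: tuple[float, float, float, float] | None
    method: str
    r_squared: float
    param_cov: np.ndarray | None = field(default=None, repr=False)
    _interp: PchipInterpolator | None = field(default=None, repr=False)

    @property
    def protein_total(self) -> float:
        return self.series.protein_total

    @property
    def _u(self) -> np.ndarray:
        lig = np.asarray(self.series.ligand)
        return np.log10(lig[lig > 0])

    def predict(self, u: np.ndarray) -> np.ndarray:
        """Fitted dF at u = log10([L]_tot)."""
        if self.method == "pchip":
            return self._interp(u)
        return _logistic4(np.asarray(u, dtype=float), *self.params)

    def dF_range(self) -> tuple[float, float]:
        """dF span of the fitted curve over the measured ligand range."""
        u = self._u
        vals = self.predict(np.array([u.min(), u.max()]))
        return float(vals[0]), float(vals[1])

    def invert(self, level: float) -> float:
        """Total ligand concentration (mol/L) at which the curve reaches dF=level."""
        lo_u, hi_u = self._u.min(), self._u.max()
        f_lo, f_hi = self.dF_range()
        if not (min(f_lo, f_hi) <= level <= max(f_lo, f_hi)):
            raise ValidationError(f"dF level {level:g} outside fitted range")
        if self.method == "pchip":
            u = optimize.brentq(lambda uu: float(self._interp(uu)) - level, lo_u, hi_u)
            return 10.0**u
        lo, hi, c, s = self.params
        arg = (hi - lo) / (level - lo) - 1.0
        if arg <= 0:
            raise ValidationError(f"dF level {level:g} not reachable by the sigmoid")
        u = c - np.log10(arg) / s
        return 10.0**u


def delta_f(
    series: TitrationSeries,
    *,
    method: str = "logistic4",
    require_corrected: bool = True,
    noise_tol: float = 0.02,
) -> QuenchCurve:
    """Compute per-point fractional quenching and fit the dF(log L) sigmoid.

    dF_i = |F_i - F0| / F0.  The zero-ligand point (dF = 0 by construction)
    anchors the curve but is excluded from the log-axis fit.  A warning is
    emitted if dF is non-monotone beyond ``noise_tol``.
    """
    if require_corrected and not series.corrected:
        raise ValidationError(
            f"series {series.label} is uncorrected; correct it first or pass "
            "require_corrected=False"
        )
    F0 = series.F0
    F = np.asarray(series.intensity)
    dF = np.abs(F - F0) / F0
    if np.allclose(dF, 0.0):
        raise ValidationError("no quenching: dF is zero everywhere")
    drops = np.diff(dF)
    if np.any(drops < -noise_tol):
        warnings.warn(
            f"series {series.label}: dF decreases by more than {noise_tol:g} "
            "between consecutive points; sigmoid fit proceeds",
            stacklevel=2,
        )
    lig = np.asarray(series.ligand)
    mask = lig > 0
    u = np.log10(lig[mask])
    y = dF[mask]
    if method == "pchip":
        order = np.argsort(u)
        # enforce strict monotonicity for the interpolant
        yy = np.maximum.accumulate(y[order])
        yy += np.arange(len(yy)) * 1e-15
        interp = PchipInterpolator(u[order], yy)
        return QuenchCurve(series, dF, None, "pchip", 1.0, _interp=interp)
    if method != "logistic4":
        raise ValidationError(f"unknown sigmoid method {method!r}")
    span = y.max() - y.min()
    p0 = (0.0, y.max() * 1.5, float(np.median(u)), 1.0)
    bounds = (
        [-0.2, 1e-6, u.min() - 3.0, 0.05],
        [0.2, 5.0, u.max() + 3.0, 10.0],
    )
    popt, pcov = optimize.curve_fit(
        _logistic4, u, y, p0=p0, bounds=bounds, maxfev=20000
    )
    resid = y - _logistic4(u, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return QuenchCurve(
        series, dF, tuple(float(p) for p in popt), "logistic4", r2, param_cov=pcov
    )


@register_result
@dataclass(frozen=True)
class IDFPoint:
    """One inverted point: free ligand (mol/L) and binding density at a dF level."""

    dF_level: float
    ppl_free: float
    binding_density: float
    usable: bool = True


def idf_invert(
    curveA: QuenchCurve,
    curveB: QuenchCurve,
    levels: list[float] | None = None,
    *,
    n_levels: int = 20,
    tail_frac: float = 0.05,
) -> list[IDFPoint]:
    """Solve mass conservation at matched dF levels of two protein concentrations.

    When ``levels`` is omitted, ``n_levels`` evenly spaced levels across the
    dF range common to both fitted curves are used, excluding the extreme
    ``tail_frac`` tails.  Points with negative binding density or free
    concentration are flagged ``usable=False`` and excluded downstream.
    The output is invariant under swapping the two curves.
    """
    P1, P2 = curveA.protein_total, curveB.protein_total
    if P1 == P2:
        raise ValidationError("IDF inversion needs two distinct protein concentrations")
    loA, hiA = curveA.dF_range()
    loB, hiB = curveB.dF_range()
    common_lo, common_hi = max(loA, loB), min(hiA, hiB)
    if levels is None:
        span = common_hi - common_lo
        levels = list(
            np.linspace(
                common_lo + tail_frac * span, common_hi - tail_frac * span, n_levels
            )
        )
    usable_levels = [lv for lv in levels if common_lo <= lv <= common_hi]
    if len(usable_levels) < len(levels):
        warnings.warn(
            f"{len(levels) - len(usable_levels)} dF level(s) outside the "
            "common fitted range dropped",
            stacklevel=2,
        )
    if not usable_levels:
        raise ValidationError("no dF level lies within both fitted curves")
    out: list[IDFPoint] = []
    for lv in usable_levels:
        L1 = curveA.invert(lv)
        L2 = curveB.invert(lv)
        nu = (L2 - L1) / (P2 - P1)
        free = L1 - nu * P1
        out.append(
            IDFPoint(
                dF_level=float(lv),
                ppl_free=float(free),
                binding_density=float(nu),
                usable=bool(nu >= 0 and free >= 0),
            )
        )
    return out


@register_result
@dataclass(frozen=True)
class ScatchardResult:
    """Scatchard coordinates (x = nu, y = nu/[L]_free) with concavity diagnostic."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    quad_coeff: float | None
    cooperativity_evidence: str  # "positive" | "negative" | "none" | "undefined"

    def summary(self) -> str:
        return (
            f"Scatchard: {len(self.x)} points, quadratic coefficient "
            f"{'undefined' if self.quad_coeff is None else format(self.quad_coeff, '.3g')}"
            f" -> {self.cooperativity_evidence} cooperativity evidence"
        )


def scatchard(points: list[IDFPoint], *, curvature_rtol: float = 0.05) -> ScatchardResult:
    """Transform IDF points to Scatchard coordinates and assess concavity.

    A least-squares parabola through (nu, nu/x) supplies the diagnostic:
    a concave-down parabola (negative quadratic coefficient, beyond
    ``curvature_rtol`` of the y scale) is evidence of positive cooperativity;
    concave-up of negative cooperativity.  Fewer than 4 points leave the
    diagnostic undefined.
    """
    pts = [p for p in points if p.usable]
    if any(p.ppl_free <= 0 for p in pts):
        raise ValidationError("Scatchard transform requires positive free-ligand values")
    x = np.array([p.binding_density for p in pts])
    y = np.array([p.binding_density / p.ppl_free for p in pts])
    if len(pts) < 4:
        return ScatchardResult(tuple(x), tuple(y), None, "undefined")
    coeffs = np.polyfit(x, y, 2)
    a = float(coeffs[0])
    # scale-free curvature: quadratic term's contribution across the x span
    scale = abs(a) * (x.max() - x.min()) ** 2 / max(np.ptp(y), abs(y).max() * 1e-3)
    if scale < curvature_rtol:
        label = "none"
    elif a < 0:
        label = "positive"
    else:
        label = "negative"
    return ScatchardResult(tuple(x), tuple(y), a, label)


def _hill(x, n, kb, h):
    z = (kb * x) ** h
    return n * z / (1.0 + z)


@register_result
@dataclass(frozen=True)
class HillResult:
    """Hill-model estimates: sites n, binding constant K_b (M^-1), coefficient h."""

    n_sites: float
    n_sites_se: float
    K_b: float
    K_b_se: float
    h: float
    h_se: float
    cooperativity_label: str
    r_squared: float
    saturation_warning: bool = False

    def summary(self) -> str:
        lines = [
            "Hill model fit",
            f"  n_sites  {self.n_sites:10.3f} +/- {self.n_sites_se:.2g}",
            f"  K_b      {self.K_b:10.4g} +/- {self.K_b_se:.2g} M^-1",
            f"  h        {self.h:10.3f} +/- {self.h_se:.2g}"
            f"  ({self.cooperativity_label} cooperativity)",
            f"  R^2      {self.r_squared:10.6f}",
        ]
        if self.saturation_warning:
            lines.append("  warning: saturation not approached; n poorly constrained")
        return "\n".join(lines)


class HillModel:
    """Nonlinear Hill isotherm fitted to (free ligand, binding density) points.

    Multistart Levenberg-Marquardt (trust-region-reflective with bounds):
    initial guesses span plausible half-saturation constants and Hill
    coefficients, the best converged solution wins.  Standard errors come
    from the fit covariance.
    """

    def __init__(self, points: list[IDFPoint]):
        pts = [p for p in points if p.usable]
        if len(pts) < 5:
            raise ValidationError(f"Hill fit needs >= 5 usable points, got {len(pts)}")
        self.x = np.array([p.ppl_free for p in pts])
        self.nu = np.array([p.binding_density for p in pts])

    def fit(self, p0: tuple[float, float, float] | None = None) -> HillResult:
        x, nu = self.x, self.nu
        nu_max = nu.max()
        kb0 = 1.0 / np.median(x)
        if p0 is not None:
            starts = [p0]
        else:
            starts = [
                (nu_max * f, kb0 * g, h0)
                for f in (1.2, 3.0)
                for g in (0.3, 1.0, 3.0)
                for h0 in (1.0, 1.5)
            ]
        # log-parameterization: enforces positivity and conditions the ridge.
        # K_b is restricted to the identifiable window: a half-saturation
        # point more than ~2 decades outside the observed free-ligand range
        # cannot be distinguished from a power law by these data.
        lo = np.log([1e-6, 1e-2 / self.x.max(), 0.05])
        hi = np.log([1e3, 1e2 / self.x.min(), 10.0])

        def resid(p):
            return _hill(x, *np.exp(p)) - nu

        scale = float(np.sum(nu**2))
        best = None
        for p0 in starts:
            try:
                r = optimize.least_squares(
                    resid, np.clip(np.log(p0), lo, hi), bounds=(lo, hi),
                    xtol=1e-15, ftol=1e-15, gtol=None, max_nfev=2000,
                )
            except ValueError:
                continue
            if best is None or r.cost < best.cost:
                best = r
            if best.cost < 1e-20 * scale:  # exact fit: no further starts needed
                break
        if best is None or not np.all(np.isfinite(best.x)):
            raise ValidationError("Hill fit failed to converge from any start")
        popt = np.exp(best.x)
        best_cost = float(2.0 * best.cost)
        n, kb, h = (float(v) for v in popt)
        # covariance on the log scale, mapped back by the delta method
        J = best.jac
        dof = max(len(x) - 3, 1)
        s2 = best_cost / dof
        try:
            cov_log = s2 * np.linalg.inv(J.T @ J)
            se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
        except np.linalg.LinAlgError:
            se_log = np.full(3, np.inf)
        n_se, kb_se, h_se = (float(p * s) for p, s in zip(popt, se_log))
        if h - 1.0 > h_se:
            label = "positive"
        elif 1.0 - h > h_se:
            label = "negative"
        else:
            label = "none"
        ss_tot = float(np.sum((nu - nu.mean()) ** 2))
        r2 = 1.0 - best_cost / ss_tot if ss_tot > 0 else 1.0
        sat_warn = bool(nu.max() < 0.5 * n and n_se > 0.5 * n)
        if sat_warn:
            warnings.warn(
                "binding-density data do not approach saturation; the fitted "
                "site number is poorly constrained",
                stacklevel=2,
            )
        return HillResult(
            n_sites=n, n_sites_se=n_se,
            K_b=kb, K_b_se=kb_se,
            h=h, h_se=h_se,
            cooperativity_label=label,
            r_squared=r2,
            saturation_warning=sat_warn,
        )


def hill_fit(points: list[IDFPoint], p0: tuple[float, float, float] | None = None) -> HillResult:
    """Functional wrapper around :class:`HillModel`."""
    return HillModel(points).fit(p0=p0)


def idf_hill_analysis(
    curveA: QuenchCurve,
    curveB: QuenchCurve,
    levels: list[float] | None = None,
    **invert_kwargs,
) -> tuple[list[IDFPoint], ScatchardResult, HillResult]:
    """Full IDF chain with uncertainty propagated from the sigmoid fits.

    Runs idf_invert -> scatchard -> hill_fit, then propagates the two
    sigmoid-fit parameter covariances through the inversion into the Hill
    parameters by the delta method (finite differences of the whole
    downstream chain).  The propagated component dominates the naive Hill
    fit covariance because every inverted point derives from the same few
    sigmoid parameters, making their errors strongly correlated.
    """
    pts = idf_invert(curveA, curveB, levels, **invert_kwargs)
    sc = scatchard(pts)
    base = hill_fit(pts)
    if (
        curveA.method != "logistic4"
        or curveB.method != "logistic4"
        or curveA.param_cov is None
        or curveB.param_cov is None
    ):
        return pts, sc, base

    fixed_levels = [p.dF_level for p in pts]
    p_all = np.concatenate([curveA.params, curveB.params])
    C = np.zeros((8, 8))
    C[:4, :4] = curveA.param_cov
    C[4:, 4:] = curveB.param_cov
    se_p = np.sqrt(np.maximum(np.diag(C), 0.0))
    base_theta = np.log([base.n_sites, base.K_b, base.h])

    def theta_at(pvec: np.ndarray) -> np.ndarray | None:
        import dataclasses as _dc

        cA = _dc.replace(curveA, params=tuple(pvec[:4]))
        cB = _dc.replace(curveB, params=tuple(pvec[4:]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pp = idf_invert(cA, cB, fixed_levels)
                hr = hill_fit(pp, p0=(base.n_sites, base.K_b, base.h))
        except ValidationError:
            return None
        return np.log([hr.n_sites, hr.K_b, hr.h])

    G = np.zeros((3, 8))
    for i in range(8):
        if se_p[i] == 0:
            continue
        step = 0.25 * se_p[i]
        for _ in range(4):
            up = theta_at(p_all + step * np.eye(8)[i])
            dn = theta_at(p_all - step * np.eye(8)[i])
            if up is not None and dn is not None:
                G[:, i] = (up - dn) / (2 * step)
                break
            step *= 0.5
    cov_log = G @ C @ G.T
    prop_se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
    vals = np.exp(base_theta)
    prop_se = vals * prop_se_log
    n_se = float(np.hypot(base.n_sites_se, prop_se[0]))
    kb_se = float(np.hypot(base.K_b_se, prop_se[1]))
    h_se = float(np.hypot(base.h_se, prop_se[2]))
    if base.h - 1.0 > h_se:
        label = "positive"
    elif 1.0 - base.h > h_se:
        label = "negative"
    else:
        label = "none"
    hr = HillResult(
        n_sites=base.n_sites, n_sites_se=n_se,
        K_b=base.K_b, K_b_se=kb_se,
        h=base.h, h_se=h_se,
        cooperativity_label=label,
        r_squared=base.r_squared,
        saturation_warning=base.saturation_warning,
    )
    return pts, sc, hr
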