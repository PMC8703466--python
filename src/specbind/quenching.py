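"""Fluorescence quenching analysis.

Covers inner-filter correction, Stern-Volmer regression, classification of
the quenching mechanism (static vs dynamic), and the double-logarithm
binding model for the association constant.

The Stern-Volmer relation for a quenched fluorophore is

    F0/F = 1 + K_SV [Q] = 1 + k_q tau0 [Q]

where K_SV is the Stern-Volmer constant, k_q the bimolecular quenching rate
and tau0 the unquenched lifetime.  Static quenching (ground-state complex
formation) is diagnosed by three independent criteria: K_SV decreasing with
temperature, lifetime ratios tau0/tau staying near unity while F0/F rises,
and k_q exceeding the diffusion-controlled limit (~1e10 M^-1 s^-1).

The double-log binding model relates the quenched fraction to the free
ligand concentration:

    log((F0-F)/F) = n log K_a + n log([Q]_free),
    [Q]_free = [Q]_tot - ((F0-F)/F0) [P]_tot

with stoichiometry n as slope and K_a recovered from the intercept.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import AnalysisConfig, TitrationPoint, TitrationSeries, ValidationError
from .io import register_result

__all__ = [
    "SternVolmerResult",
    "MechanismVerdict",
    "DoubleLogResult",
    "SternVolmer",
    "DoubleLog",
    "inner_filter_correct",
    "stern_volmer_fit",
    "double_log_fit",
    "classify_mechanism",
]


def inner_filter_correct(
    series: TitrationSeries, config: AnalysisConfig | None = None
) -> TitrationSeries:
    """Correct observed intensities for inner-filter attenuation.

    Applies ``F_corr = F_obs * 10**((a*A_ex + b*A_em)/10)`` per point with
    (a, b) from the configuration (default (5, 1), the 2 mm x 10 mm cuvette
    geometry with absorbances read over a 10 mm path).  Points without
    absorbances pass through unchanged with a warning.  Raises if the series
    is already corrected, preventing double correction.
    """
    cfg = config or AnalysisConfig()
    if series.corrected:
        raise ValidationError(f"series {series.label} is already inner-filter corrected")
    out: list[TitrationPoint] = []
    n_skipped = 0
    for p in series.points:
        if p.A_ex is None or p.A_em is None:
            out.append(p)
            n_skipped += 1
            continue
        factor = 10.0 ** ((cfg.ifc_a * p.A_ex + cfg.ifc_b * p.A_em) / 10.0)
        out.append(
            TitrationPoint(
                ligand_total=p.ligand_total,
                F_obs=p.F_obs * factor,
                A_ex=p.A_ex,
                A_em=p.A_em,
            )
        )
    if n_skipped:
        warnings.warn(
            f"series {series.label}: {n_skipped} point(s) lack absorbances; "
            "passed through uncorrected",
            stacklevel=2,
        )
    return series.with_points(out, corrected=True)


@register_result
@dataclass(frozen=True)
class SternVolmerResult:
    """Stern-Volmer regression estimates."""

    K_SV: float
    K_SV_se: float
    intercept: float
    intercept_se: float
    temperature: float
    r_squared: float
    k_q: float | None = None
    k_q_se: float | None = None

    def summary(self) -> str:
        lines = [
            "Stern-Volmer fit",
            f"  T          {self.temperature:10.1f} K",
            f"  K_SV       {self.K_SV:10.4g} +/- {self.K_SV_se:.2g} M^-1",
            f"  intercept  {self.intercept:10.4f} +/- {self.intercept_se:.2g}",
            f"  R^2        {self.r_squared:10.5f}",
        ]
        if self.k_q is not None:
            lines.append(f"  k_q        {self.k_q:10.4g} +/- {self.k_q_se:.2g} M^-1 s^-1")
        return "\n".join(lines)


class SternVolmer:
    """Linear Stern-Volmer model F0/F = 1 + K_SV [Q] fitted by OLS.

    Parameters
    ----------
    series : TitrationSeries
        Corrected titration (or pass ``require_corrected=False`` for data
        that needs no inner-filter correction).
    tau0 : float, optional
        Unquenched lifetime in seconds; when given, the bimolecular rate
        k_q = K_SV / tau0 is reported.
    """

    def __init__(
        self,
        series: TitrationSeries,
        tau0: float | None = None,
        *,
        require_corrected: bool = True,
    ):
        if require_corrected and not series.corrected:
            raise ValidationError(
                f"series {series.label} is uncorrected; correct it first or "
                "pass require_corrected=False"
            )
        if len(series.points) < 3:
            raise ValidationError("Stern-Volmer fit needs at least 3 points")
        if any(p.F_obs <= 0 for p in series.points):
            raise ValidationError("non-positive intensity in series")
        self.series = series
        self.tau0 = tau0

    def fit(self) -> SternVolmerResult:
        q = np.asarray(self.series.ligand)
        ratio = self.series.F0 / np.asarray(self.series.intensity)
        res = stats.linregress(q, ratio)
        k_q = k_q_se = None
        if self.tau0 is not None:
            if self.tau0 <= 0:
                raise ValidationError("tau0 must be > 0")
            k_q = res.slope / self.tau0
            k_q_se = res.stderr / self.tau0
        return SternVolmerResult(
            K_SV=float(res.slope),
            K_SV_se=float(res.stderr),
            intercept=float(res.intercept),
            intercept_se=float(res.intercept_stderr),
            temperature=self.series.temperature,
            r_squared=float(res.rvalue**2),
            k_q=k_q,
            k_q_se=k_q_se,
        )


def stern_volmer_fit(
    series: TitrationSeries, tau0: float | None = None, *, require_corrected: bool = True
) -> SternVolmerResult:
    """Functional wrapper around :class:`SternVolmer`."""
    return SternVolmer(series, tau0, require_corrected=require_corrected).fit()


@register_result
@dataclass(frozen=True)
class MechanismVerdict:
    """Outcome of the three-way quenching-mechanism test.

    ``verdict`` is "static" only when at least two criteria support a static
    mechanism and none contradicts it; mirrored for "dynamic"; anything else
    is "ambiguous".
    """

    verdict: str
    ksv_decreasing: bool | None
    tau_ratio_flat: bool | None
    kq_exceeds_limit: bool | None
    evidence: dict = field(default_factory=dict)

    def summary(self) -> str:
        def show(v):
            return "n/a" if v is None else ("yes" if v else "no")

        return "\n".join(
            [
                f"Quenching mechanism: {self.verdict.upper()}",
                f"  K_SV decreases with T       : {show(self.ksv_decreasing)}",
                f"  tau0/tau ~ 1 while F0/F > 1 : {show(self.tau_ratio_flat)}",
                f"  k_q above diffusion limit   : {show(self.kq_exceeds_limit)}",
            ]
        )


def classify_mechanism(
    sv_results: list[SternVolmerResult],
    lifetime_ratios: list[tuple[float, float]] | None = None,
    diffusion_limit: float = 1e10,
    config: AnalysisConfig | None = None,
) -> MechanismVerdict:
    """Classify quenching as static, dynamic or ambiguous.

    Parameters
    ----------
    sv_results : list of SternVolmerResult
        Fits at two or more temperatures (any order) for the trend test.
    lifetime_ratios : list of (F0/F, tau0/tau), optional
        Paired steady-state and lifetime ratios at matching quencher
        concentrations.
    diffusion_limit : float
        Diffusion-controlled upper bound on k_q (M^-1 s^-1).

    The temperature-trend criterion requires K_SV strictly decreasing with
    increasing T with each step larger than the sum of the two standard
    errors (a significance guard for the few-temperature case).
    """
    cfg = config or AnalysisConfig()
    evidence: dict = {}

    ksv_dec: bool | None = None
    if len(sv_results) >= 2:
        ordered = sorted(sv_results, key=lambda r: r.temperature)
        steps = [
            (a.K_SV - b.K_SV, a.K_SV_se + b.K_SV_se)
            for a, b in zip(ordered, ordered[1:])
        ]
        ksv_dec = all(drop > se_sum for drop, se_sum in steps)
        ksv_inc = all(-drop > se_sum for drop, se_sum in steps)
        evidence["K_SV_by_T"] = {r.temperature: r.K_SV for r in ordered}
        evidence["ksv_increasing"] = ksv_inc
    else:
        ksv_inc = False

    tau_flat: bool | None = None
    if lifetime_ratios:
        f_ratios = [f for f, _ in lifetime_ratios]
        t_ratios = [t for _, t in lifetime_ratios]
        tol = cfg.tau_ratio_tol
        quenched = max(f_ratios) - 1.0 > tol
        ratios_equal = all(abs(f - t) <= tol for f, t in lifetime_ratios)
        tau_flat = quenched and all(abs(t - 1.0) <= tol for t in t_ratios)
        evidence["max_F0_over_F"] = max(f_ratios)
        evidence["max_abs_tau_ratio_dev"] = max(abs(t - 1.0) for t in t_ratios)
        evidence["F_equals_tau_ratios"] = ratios_equal
    else:
        ratios_equal = False

    kq_high: bool | None = None
    kqs = [r.k_q for r in sv_results if r.k_q is not None]
    if kqs:
        kq_high = all(k > diffusion_limit for k in kqs)
        kq_low = all(k <= diffusion_limit for k in kqs)
        evidence["k_q"] = kqs
    else:
        kq_low = False

    static_votes = sum(bool(v) for v in (ksv_dec, tau_flat, kq_high))
    dynamic_votes = sum(bool(v) for v in (ksv_inc, ratios_equal and not tau_flat, kq_low))
    static_contra = any(v for v in (ksv_inc, kq_low)) or (
        lifetime_ratios and ratios_equal and not tau_flat
    )
    dynamic_contra = any(bool(v) for v in (ksv_dec, tau_flat, kq_high))

    if static_votes >= 2 and not static_contra:
        verdict = "static"
    elif dynamic_votes >= 2 and not dynamic_contra:
        verdict = "dynamic"
    else:
        verdict = "ambiguous"
    return MechanismVerdict(
        verdict=verdict,
        ksv_decreasing=ksv_dec,
        tau_ratio_flat=tau_flat,
        kq_exceeds_limit=kq_high,
        evidence=evidence,
    )


@register_result
@dataclass(frozen=True)
class DoubleLogResult:
    """Double-log binding fit: association constant and stoichiometry."""

    K_a: float
    K_a_se: float
    n_stoich: float
    n_stoich_se: float
    temperature: float
    r_squared: float
    n_points_used: int

    def summary(self) -> str:
        return "\n".join(
            [
                "Double-log binding fit",
                f"  T        {self.temperature:10.1f} K",
                f"  K_a      {self.K_a:10.4g} +/- {self.K_a_se:.2g} M^-1",
                f"  n        {self.n_stoich:10.3f} +/- {self.n_stoich_se:.2g}",
                f"  R^2      {self.r_squared:10.5f}   ({self.n_points_used} points)",
            ]
        )


class DoubleLog:
    """Double-logarithm binding model fitted by linear regression.

    Regresses log10((F0-F)/F) on log10([Q]_free) where the free quencher
    concentration accounts for ligand depletion by binding:
    [Q]_free = [Q]_tot - ((F0-F)/F0) [P]_tot.  The slope is the apparent
    stoichiometry n; K_a comes from intercept = n log10 K_a.  Points with
    F >= F0 or non-positive depleted concentration are excluded (with a
    warning for the latter).
    """

    def __init__(self, series: TitrationSeries, *, require_corrected: bool = True):
        if require_corrected and not series.corrected:
            raise ValidationError(
                f"series {series.label} is uncorrected; correct it first or "
                "pass require_corrected=False"
            )
        self.series = series

    def fit(self) -> DoubleLogResult:
        s = self.series
        F0 = s.F0
        lig = np.asarray(s.ligand)
        F = np.asarray(s.intensity)
        quenched = F < F0
        quenched[0] = False  # zero-ligand point never enters
        if not np.any(quenched[1:]):
            raise ValidationError("no quenching observed (F >= F0 everywhere)")
        y_ratio = (F0 - F[quenched]) / F[quenched]
        free = lig[quenched] - ((F0 - F[quenched]) / F0) * s.protein_total
        usable = free > 0
        if np.sum(~usable):
            warnings.warn(
                f"{int(np.sum(~usable))} point(s) with non-positive depleted "
                "free-ligand concentration excluded",
                stacklevel=2,
            )
        if np.sum(usable) < 4:
            raise ValidationError(
                "double-log fit needs >= 4 usable quenched points, "
                f"got {int(np.sum(usable))}"
            )
        x = np.log10(free[usable])
        y = np.log10(y_ratio[usable])
        res = stats.linregress(x, y)
        n = res.slope
        if n <= 0:
            raise ValidationError("fitted stoichiometry is non-positive")
        log_ka = res.intercept / n
        ka = 10.0**log_ka
        # first-order propagation: Ka = 10^(b/n), d/db and d/dn terms
        dka_db = ka * math.log(10) / n
        dka_dn = -ka * math.log(10) * res.intercept / n**2
        ka_se = math.hypot(dka_db * res.intercept_stderr, dka_dn * res.stderr)
        return DoubleLogResult(
            K_a=float(ka),
            K_a_se=float(ka_se),
            n_stoich=float(n),
            n_stoich_se=float(res.stderr),
            temperature=s.temperature,
            r_squared=float(res.rvalue**2),
            n_points_used=int(np.sum(usable)),
        )


def double_log_fit(
    series: TitrationSeries, *, require_corrected: bool = True
) -> DoubleLogResult:
    """Functional wrapper around :class:`DoubleLog`."""
    return DoubleLog(series, require_corrected=require_corrected).fit()
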