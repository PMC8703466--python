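"""Optional static diagnostic plots (requires matplotlib)."""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_quench_curve(curve, ax=None):
    """dF vs log10 total ligand with the fitted sigmoid."""
    ax = _ax(ax)
    lig = np.asarray(curve.series.ligand)
    mask = lig > 0
    u = np.log10(lig[mask])
    ax.plot(u, curve.dF[mask], "o", label=f"P = {curve.protein_total:.2g} M")
    uu = np.linspace(u.min(), u.max(), 200)
    ax.plot(uu, curve.predict(uu), "-")
    ax.set_xlabel("log10 [ligand] (M)")
    ax.set_ylabel("dF")
    ax.legend()
    return ax


def plot_scatchard(result, ax=None):
    """Scatchard plot (nu/x vs nu) with the diagnostic parabola."""
    ax = _ax(ax)
    x = np.asarray(result.x)
    y = np.asarray(result.y)
    ax.plot(x, y, "o")
    if result.quad_coeff is not None and len(x) >= 4:
        coeffs = np.polyfit(x, y, 2)
        xx = np.linspace(x.min(), x.max(), 100)
        ax.plot(xx, np.polyval(coeffs, xx), "--")
    ax.set_xlabel("binding density (nu)")
    ax.set_ylabel("nu / [L]free (M$^{-1}$)")
    return ax


def plot_melt(result, series=None, ax=None):
    """Fitted two-state melt over the measured ellipticities."""
    ax = _ax(ax)
    T = np.asarray(result.temperature_K)
    if series is not None:
        ax.plot(series.temperature_K, series.theta_mdeg, "o", ms=3)
    model = result.theta_nat + (result.theta_den - result.theta_nat) / (
        1.0 + np.exp((result.Tm - T) / result.width)
    )
    ax.plot(T, model, "-")
    ax.axvline(result.Tm, ls=":", label=f"Tm = {result.Tm:.1f} K")
    ax.set_xlabel("T (K)")
    ax.set_ylabel("ellipticity (mdeg)")
    ax.legend()
    return ax
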