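"""Combined analysis pipeline and report bundle.

Orchestrates the full spectroscopic workflow over whatever inputs are
available: inner-filter correction, Stern-Volmer fits per temperature,
quenching-mechanism classification, double-log binding fits, Van't Hoff
thermodynamics, IDF/Scatchard/Hill cooperativity (when a protein
concentration pair is present), lifetime fits and CD melting.  Partial
inputs yield partial reports; a failing stage is recorded and does not
abort the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .datamodel import AnalysisConfig, TitrationSeries, ValidationError
from .io import read_cd_melt_csv, read_decay_csv, read_titration_csv, register_result
from .quenching import (
    classify_mechanism,
    double_log_fit,
    inner_filter_correct,
    stern_volmer_fit,
)
from .thermodynamics import vant_hoff_fit
from .idf import delta_f, idf_hill_analysis
from .lifetime import fit_decay, lifetime_ratio_series
from .cd import fit_melting

__all__ = ["PipelineInputs", "ReportBundle", "run_full_pipeline"]


@dataclass
class PipelineInputs:
    """File paths and per-run options for the full pipeline."""

    titrations: str | Path | None = None
    decays: list[str | Path] = field(default_factory=list)
    melt: str | Path | None = None
    tau0: float | None = None  # seconds; enables k_q
    idf_pair: tuple[float, float] | None = None  # protein concentrations, mol/L
    n_components: int = 2
    melt_n_residues: int | None = None
    melt_protein_conc: float | None = None
    melt_path_cm: float | None = None


@register_result
@dataclass
class ReportBundle:
    """All per-stage results plus provenance; every summary number traces here."""

    sv_results: list = field(default_factory=list)
    mechanism: object | None = None
    double_log_results: list = field(default_factory=list)
    thermo: object | None = None
    hill: object | None = None
    scatchard_result: object | None = None
    idf_points: list = field(default_factory=list)
    lifetimes: list = field(default_factory=list)
    lifetime_ratios: list = field(default_factory=list)
    melt: object | None = None
    errors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def summary(self) -> str:
        parts = ["=" * 60, "specbind analysis report", "=" * 60]
        if self.sv_results:
            parts.append("\n-- Stern-Volmer / mechanism --")
            parts += [r.summary() for r in self.sv_results]
            if self.mechanism is not None:
                parts.append(self.mechanism.summary())
        if self.double_log_results:
            parts.append("\n-- Double-log binding --")
            parts += [r.summary() for r in self.double_log_results]
        if self.thermo is not None:
            parts.append("\n-- Thermodynamics --")
            parts.append(self.thermo.summary())
        if self.hill is not None:
            parts.append("\n-- IDF / Scatchard / Hill --")
            parts.append(self.scatchard_result.summary())
            parts.append(self.hill.summary())
        if self.lifetimes:
            parts.append("\n-- Lifetimes --")
            parts += [r.summary() for r in self.lifetimes]
        if self.melt is not None:
            parts.append("\n-- CD melting --")
            parts.append(self.melt.summary())
        absent = []
        if self.thermo is None:
            absent.append("thermodynamics")
        if self.hill is None:
            absent.append("IDF/Hill")
        if not self.lifetimes:
            absent.append("lifetimes")
        if self.melt is None:
            absent.append("CD melting")
        if absent:
            parts.append("\nabsent sections (no input): " + ", ".join(absent))
        if self.errors:
            parts.append("\nstage errors:")
            parts += [f"  {k}: {v}" for k, v in self.errors.items()]
        return "\n".join(parts)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _prepare(series: TitrationSeries, config: AnalysisConfig) -> TitrationSeries:
    if series.corrected:
        return series
    has_abs = all(p.A_ex is not None and p.A_em is not None for p in series.points)
    if has_abs:
        return inner_filter_correct(series, config)
    # no absorbances recorded: analysed as-is
    return series.with_points(series.points, corrected=True)


def run_full_pipeline(
    config: AnalysisConfig | None = None, paths: PipelineInputs | None = None
) -> ReportBundle:
    """Run every stage the inputs support and collect a ReportBundle."""
    cfg = config or AnalysisConfig()
    inputs = paths or PipelineInputs()
    bundle = ReportBundle()
    prov: dict = {"version": __version__, "config": vars(cfg).copy(), "inputs": {}}

    all_series: list[TitrationSeries] = []
    if inputs.titrations is not None:
        try:
            all_series = [
                _prepare(s, cfg) for s in read_titration_csv(inputs.titrations, cfg)
            ]
            prov["inputs"]["titrations"] = _sha256(inputs.titrations)
        except Exception as err:
            bundle.errors["read_titrations"] = str(err)
            all_series = []

    # lifetimes first: their ratios feed the mechanism verdict
    if inputs.decays:
        for p in inputs.decays:
            try:
                curve = read_decay_csv(p, cfg)
                bundle.lifetimes.append(fit_decay(curve, inputs.n_components, cfg))
                prov["inputs"][f"decay:{p}"] = _sha256(p)
            except Exception as err:
                bundle.errors[f"lifetime:{p}"] = str(err)
        if bundle.lifetimes:
            try:
                bundle.lifetime_ratios = lifetime_ratio_series(bundle.lifetimes)
            except Exception as err:
                bundle.errors["lifetime_ratios"] = str(err)

    if all_series:
        # Stern-Volmer per series; trend taken across temperatures at the
        # protein concentration measured at the most temperatures.
        for s in all_series:
            try:
                bundle.sv_results.append(stern_volmer_fit(s, inputs.tau0))
            except Exception as err:
                bundle.errors[f"stern_volmer:{s.label}"] = str(err)
        try:
            ratios = None
            if bundle.lifetime_ratios and bundle.sv_results:
                by_lig = {
                    round(p.ligand_total, 12): bundle.sv_results[0]
                    for p in all_series[0].points
                }
                F0 = all_series[0].F0
                f_by_lig = {
                    round(p.ligand_total, 12): F0 / p.F_obs
                    for p in all_series[0].points
                }
                ratios = [
                    (f_by_lig[round(L, 12)], r)
                    for L, r in bundle.lifetime_ratios
                    if round(L, 12) in f_by_lig
                ]
            bundle.mechanism = classify_mechanism(
                bundle.sv_results, ratios or None, cfg.diffusion_limit, cfg
            )
        except Exception as err:
            bundle.errors["mechanism"] = str(err)

        ka_by_T: dict[float, tuple[float, float]] = {}
        for s in all_series:
            try:
                dl = double_log_fit(s)
                bundle.double_log_results.append(dl)
                ka_by_T[s.temperature] = (dl.K_a, dl.K_a_se)
            except Exception as err:
                bundle.errors[f"double_log:{s.label}"] = str(err)
        if len(ka_by_T) >= 3:
            try:
                bundle.thermo = vant_hoff_fit(ka_by_T)
            except Exception as err:
                bundle.errors["vant_hoff"] = str(err)

        # IDF needs two distinct protein concentrations at one temperature
        try:
            pair = _select_idf_pair(all_series, inputs.idf_pair)
            if pair is not None:
                cA, cB = delta_f(pair[0]), delta_f(pair[1])
                pts, sc, hill = idf_hill_analysis(cA, cB)
                bundle.idf_points = pts
                bundle.scatchard_result = sc
                bundle.hill = hill
        except Exception as err:
            bundle.errors["idf"] = str(err)

    if inputs.melt is not None:
        try:
            series = read_cd_melt_csv(
                inputs.melt,
                protein_conc=inputs.melt_protein_conc,
                path_cm=inputs.melt_path_cm,
                n_residues=inputs.melt_n_residues,
            )
            bundle.melt = fit_melting(series)
            prov["inputs"]["melt"] = _sha256(inputs.melt)
        except Exception as err:
            bundle.errors["melt"] = str(err)

    bundle.provenance = prov
    return bundle


def _select_idf_pair(
    all_series: list[TitrationSeries], requested: tuple[float, float] | None
) -> tuple[TitrationSeries, TitrationSeries] | None:
    if requested is not None:
        sel = []
        for conc in requested:
            match = [
                s
                for s in all_series
                if abs(s.protein_total - conc) <= 1e-9 + 1e-6 * conc
            ]
            if not match:
                raise ValidationError(
                    f"no titration series at protein concentration {conc:g} M"
                )
            sel.append(match[0])
        return sel[0], sel[1]
    by_T: dict[float, list[TitrationSeries]] = {}
    for s in all_series:
        by_T.setdefault(s.temperature, []).append(s)
    for T, group in sorted(by_T.items()):
        concs = sorted({s.protein_total for s in group})
        if len(concs) >= 2:
            a = next(s for s in group if s.protein_total == concs[0])
            b = next(s for s in group if s.protein_total == concs[-1])
            return a, b
    return None
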