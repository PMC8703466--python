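"""CSV readers and JSON result serialisation.

CSV dialect: comma-separated, '.' decimal, optional ``#``-prefixed metadata
header lines of the form ``# key=value`` (e.g. ``# unit=uM``).  Concentrations
are converted to mol/L from the unit declared in the header (or in the
:class:`~specbind.datamodel.AnalysisConfig`).

Result records are serialised to JSON with a type tag so that
``read_results_json(write_results_json(x)) == x``.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from pathlib import Path
from typing import Any

import pandas as pd

from .datamodel import (
    AnalysisConfig,
    CDMeltSeries,
    DecayCurve,
    TitrationPoint,
    TitrationSeries,
    UNIT_FACTORS,
    ValidationError,
)

__all__ = [
    "read_titration_csv",
    "read_decay_csv",
    "read_cd_melt_csv",
    "write_results_json",
    "read_results_json",
    "register_result",
]


def _split_metadata(text: str) -> tuple[dict[str, str], str]:
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in text.splitlines():
        if line.lstrip().startswith("#"):
            stripped = line.lstrip().lstrip("#").strip()
            if "=" in stripped:
                key, _, val = stripped.partition("=")
                meta[key.strip()] = val.strip()
        else:
            body.append(line)
    return meta, "\n".join(body)


def _read_table(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    text = Path(path).read_text()
    meta, body = _split_metadata(text)
    df = pd.read_csv(_io.StringIO(body))
    df.columns = [c.strip() for c in df.columns]
    return meta, df


def _unit_factor(meta: dict[str, str], config: AnalysisConfig | None) -> float:
    unit = meta.get("unit", (config or AnalysisConfig()).concentration_unit)
    if unit not in UNIT_FACTORS:
        raise ValidationError(f"unknown concentration unit {unit!r} in file header")
    return UNIT_FACTORS[unit]


def read_titration_csv(
    path: str | Path, config: AnalysisConfig | None = None
) -> list[TitrationSeries]:
    """Read titration data, one series per (protein_total, temperature) group.

    Required columns: ``protein_total, temperature, ligand_total, F_obs``;
    optional: ``A_ex, A_em``.  Each series must contain a ``ligand_total = 0``
    row (the F0 point) and a strictly increasing ligand column.
    """
    meta, df = _read_table(path)
    required = {"protein_total", "temperature", "ligand_total", "F_obs"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    factor = _unit_factor(meta, config)

    series: list[TitrationSeries] = []
    for (prot, temp), group in df.groupby(["protein_total", "temperature"], sort=True):
        group = group.sort_values("ligand_total")
        label = f"P={prot:g}, T={temp:g}"
        if group["ligand_total"].iloc[0] != 0:
            raise ValidationError(
                f"series {label}: no ligand_total=0 row, F0 undefined"
            )
        points = []
        for _, row in group.iterrows():
            points.append(
                TitrationPoint(
                    ligand_total=float(row["ligand_total"]) * factor,
                    F_obs=float(row["F_obs"]),
                    A_ex=float(row["A_ex"]) if "A_ex" in group and pd.notna(row.get("A_ex")) else None,
                    A_em=float(row["A_em"]) if "A_em" in group and pd.notna(row.get("A_em")) else None,
                )
            )
        series.append(
            TitrationSeries(
                protein_total=float(prot) * factor,
                temperature=float(temp),
                points=tuple(points),
                corrected=meta.get("corrected", "false").lower() == "true",
                label=label,
            )
        )
    return series


def read_decay_csv(path: str | Path, config: AnalysisConfig | None = None) -> DecayCurve:
    """Read a TCSPC histogram with columns ``time_ns, counts``."""
    meta, df = _read_table(path)
    missing = {"time_ns", "counts"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    ligand = float(meta.get("ligand_total", 0.0)) * (
        _unit_factor(meta, config) if "ligand_total" in meta else 1.0
    )
    return DecayCurve(
        time_bins=tuple(df["time_ns"].astype(float)),
        counts=tuple(df["counts"].astype(int)),
        ligand_total=ligand,
    )


def read_cd_melt_csv(
    path: str | Path,
    *,
    protein_conc: float | None = None,
    path_cm: float | None = None,
    n_residues: int | None = None,
    monitor_wavelength: float | None = None,
) -> CDMeltSeries:
    """Read a CD melting series with columns ``temperature_K, theta_mdeg``.

    Sample parameters may be given in the file header (``# protein_conc=...``,
    mol/L) or as keyword overrides; keywords win.
    """
    meta, df = _read_table(path)
    missing = {"temperature_K", "theta_mdeg"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")

    def pick(kw, key, cast=float):
        if kw is not None:
            return kw
        if key in meta:
            return cast(meta[key])
        raise ValidationError(f"{path}: {key} missing from header and not supplied")

    return CDMeltSeries(
        temperature_K=tuple(df["temperature_K"].astype(float)),
        theta_mdeg=tuple(df["theta_mdeg"].astype(float)),
        monitor_wavelength=pick(monitor_wavelength, "monitor_wavelength"),
        protein_conc=pick(protein_conc, "protein_conc"),
        path_cm=pick(path_cm, "path_cm"),
        n_residues=pick(n_residues, "n_residues", int),
    )


# --- JSON result records -------------------------------------------------

_RESULT_REGISTRY: dict[str, type] = {}


def register_result(cls):
    """Class decorator: make a result dataclass JSON round-trippable."""
    _RESULT_REGISTRY[cls.__name__] = cls
    return cls


def _encode(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload = {
            f.name: _encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
        return {"__type__": type(obj).__name__, **payload}
    if isinstance(obj, dict):
        # JSON keys are strings; numeric keys (e.g. temperatures) are restored
        # on read because the dataclass field order fixes their type.
        return {str(k): _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


def _decode(obj: Any) -> Any:
    if isinstance(obj, dict) and "__type__" in obj:
        name = obj["__type__"]
        cls = _RESULT_REGISTRY.get(name)
        if cls is None:
            raise ValidationError(f"unknown result type {name!r} in JSON")
        kwargs = {k: _decode(v) for k, v in obj.items() if k != "__type__"}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for k, f in fields.items():
            if k in kwargs and isinstance(kwargs[k], dict) and "float" in str(f.type):
                kwargs[k] = {float(kk): vv for kk, vv in kwargs[k].items()}
            if k in kwargs and isinstance(kwargs[k], list) and "tuple" in str(f.type):
                kwargs[k] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in kwargs[k]
                )
        return cls(**kwargs)
    if isinstance(obj, dict):
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def write_results_json(results: Any, path: str | Path) -> None:
    """Serialise a result record (or list/dict of records) to JSON."""
    Path(path).write_text(json.dumps(_encode(results), indent=2, allow_nan=True))


def read_results_json(path: str | Path) -> Any:
    """Inverse of :func:`write_results_json`."""
    return _decode(json.loads(Path(path).read_text()))
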