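"""Shared table readers, report writers and the pipeline driver."""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__

__all__ = [
    "read_table",
    "read_spectrum",
    "write_report",
    "fuel_properties_markdown",
    "RunConfig",
    "PipelineError",
    "run_pipeline",
]


def _split_pm(series: pd.Series) -> tuple[pd.Series, pd.Series | None]:
    """Split '58.1 ± 1.8'-style cells into mean and sd."""
    if series.dtype != object:
        return series, None
    stripped = series.astype(str).str.strip()
    if not stripped.str.contains("±").any():
        return series, None
    parts = stripped.str.split("±", n=1, expand=True)
    mean = pd.to_numeric(parts[0].str.strip(), errors="coerce")
    sd = pd.to_numeric(parts[1].str.strip(), errors="coerce") if parts.shape[1] > 1 else None
    return mean, sd


def read_table(
    source,
    required: Sequence[str] = (),
    numeric: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with a header row.

    The delimiter is sniffed. Columns containing ``±`` are split into a
    numeric mean column (same name) plus a ``<name>_sd`` column. Missing
    required columns and non-numeric cells in ``numeric`` columns raise
    with the offending column / row named.
    """
    df = pd.read_csv(source, sep=None, engine="python", skip_blank_lines=True)
    if df.empty and df.columns.size == 0:
        raise ValueError("empty table: no header row found")
    df.columns = [str(c).strip() for c in df.columns]
    for col in list(df.columns):
        mean, sd = _split_pm(df[col])
        df[col] = mean
        if sd is not None:
            df[f"{col}_sd"] = sd
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}; found {list(df.columns)}")
    for col in numeric:
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value in column {col!r} at row {int(bad[0])}: "
                f"{df.loc[bad[0], col]!r}"
            )
        df[col] = converted
    return df


def read_spectrum(source, kind: str = "uvvis"):
    """Read a two-column (abscissa, absorbance) delimited file.

    A header row is optional; FTIR files with descending wavenumbers are
    accepted (the Spectrum re-sorts them ascending).
    """
    from .pigment import Spectrum

    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    has_header = any(ch.isalpha() for ch in first.replace("e", "").replace("E", ""))
    df = pd.read_csv(
        _io.StringIO(text), sep=None, engine="python",
        header=0 if has_header else None,
    )
    if df.shape[1] < 2:
        raise ValueError("spectrum file needs two columns: abscissa, absorbance")
    return Spectrum(
        x=df.iloc[:, 0].to_numpy(dtype=float),
        y=df.iloc[:, 1].to_numpy(dtype=float),
        kind=kind,
    )


def _jsonable(obj: Any) -> Any:
    if hasattr(obj, "as_dict"):
        return _jsonable(obj.as_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def write_report(
    results: dict,
    path: str | Path,
    format: str = "json",
    config_echo: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write a results report as machine-diffable JSON or a markdown table.

    JSON output is deterministic (sorted keys, fixed separators, no
    timestamps): identical results produce byte-identical files.
    """
    path = Path(path)
    payload = {
        "package_version": __version__,
        "seed": seed,
        "config": _jsonable(config_echo or {}),
        "results": _jsonable(results),
    }
    if format == "json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "markdown":
        lines = [f"# mycorefinery report (v{__version__})", ""]
        for stage, res in payload["results"].items():
            lines.append(f"## {stage}")
            lines.append("")
            if stage == "fuel_properties" and isinstance(res, dict):
                lines.extend(fuel_properties_markdown(res).splitlines())
            else:
                lines.append("```json")
                lines.append(json.dumps(res, indent=2, sort_keys=True))
                lines.append("```")
            lines.append("")
        path.write_text("\n".join(lines))
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


_PROPERTY_ROWS = [
    ("density", "Density, rho at 15 degC", "kg m^-3", 1),
    ("kinematic_viscosity", "Kinematic viscosity, nu at 40 degC", "mm^2 s^-1", 2),
    ("saponification_number", "Saponification number, SN", "mg KOH g^-1", 2),
    ("iodine_value", "Iodine value, IV", "g I2/100 g", 2),
    ("higher_heating_value", "Higher heating value, HHV", "MJ kg^-1", 2),
    ("cetane_number", "Cetane number, CN", "", 1),
]


def fuel_properties_markdown(props: dict) -> str:
    """Markdown table of the six fuel properties (presentation rounding only)."""
    lines = ["| Property | Value | Unit |", "| --- | --- | --- |"]
    for key, label, unit, nd in _PROPERTY_ROWS:
        if key in props:
            lines.append(f"| {label} | {props[key]:.{nd}f} | {unit} |")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# pipeline


_STAGES = ("fame", "ferment", "pigment", "chitosan")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``inputs`` maps stage names to input file paths (stages without an
    input fall back to the packaged study fixtures); ``params`` holds
    stage parameters (``sn_constant``, ``mixing``, ``policy``,
    ``stability_threshold``, ...). Unknown stages or parameter keys are
    rejected up front.
    """

    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    out_dir: str = "mycorefinery_out"
    seed: int = 0
    verbose: bool = False

    _KNOWN_PARAMS = {
        "sn_constant", "mixing", "policy", "standard",
        "stability_threshold", "ec50_level", "peak_prominence",
    }

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in _STAGES:
                raise ValueError(f"unknown stage {stage!r}; supported: {_STAGES}")
        for stage in self.inputs:
            if stage not in _STAGES:
                raise ValueError(f"input given for unknown stage {stage!r}")
        unknown = set(self.params) - self._KNOWN_PARAMS
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage_fame(config: RunConfig) -> dict:
    from . import datasets
    from .fame import check_compliance, compute_fuel_properties, parse_fame_table

    if "fame" in config.inputs:
        profile = parse_fame_table(config.inputs["fame"])
    else:
        profile = datasets.load_fame_profile()
    props = compute_fuel_properties(
        profile,
        sn_constant=config.params.get("sn_constant", 560.0),
        mixing=config.params.get("mixing", "linear"),
        policy=config.params.get("policy", "homolog"),
    )
    return {
        "fuel_properties": props.as_dict(),
        "constants_record": props.constants_record,
        "compliance": {
            name: check_compliance(props, name).as_dict()
            for name in ("EN 14214", "ASTM D6751")
        },
    }


def _stage_ferment(config: RunConfig) -> dict:
    from . import datasets
    from .fermentation import derive_table, find_optimum, rank_treatments

    if "ferment" in config.inputs:
        df = read_table(
            config.inputs["ferment"],
            required=("substrate_conc", "total_sugar", "dry_weight", "lipid_conc"),
        )
    else:
        df = datasets.load_substrate_series()
    derived = derive_table(df)
    optimum = find_optimum(
        list(zip(df["substrate_conc"], df["lipid_conc"])), response="lipid_conc"
    )
    ranking = rank_treatments(datasets.load_pretreatment_observations(), "lipid_conc")
    return {
        "derived_table": derived.to_dict(orient="records"),
        "optimum": {
            "substrate_conc": optimum.substrate_conc,
            "lipid_conc": optimum.response,
            "tie": optimum.tie,
        },
        "top_pretreatment": ranking[0][0].treatment_label,
    }


def _stage_pigment(config: RunConfig) -> dict:
    from . import datasets
    from .pigment import detect_peaks, ec50_interpolate
    from .synthetic import SpectrumSpec, make_spectrum

    if "pigment" in config.inputs:
        spectrum = read_spectrum(config.inputs["pigment"])
    else:
        spectrum, _ = make_spectrum(SpectrumSpec(seed=config.seed))
    peaks = detect_peaks(
        spectrum, prominence=config.params.get("peak_prominence")
    )
    dr = datasets.load_pigment_dose_response()
    ec50 = ec50_interpolate(dr, level=config.params.get("ec50_level", 50.0))
    return {
        "peaks": [{"position": p.position, "height": p.height} for p in peaks],
        "ec50_ug_ml": ec50.value,
        "ec50_bracket": ec50.bracket,
    }


def _stage_chitosan(config: RunConfig) -> dict:
    from .chitosan import chitosan_yield, composite_metrics, degree_of_deacetylation
    from .synthetic import make_ftir_dd_spectrum

    if "chitosan" in config.inputs:
        spectrum = read_spectrum(config.inputs["chitosan"], kind="ftir")
    else:
        spectrum, _ = make_ftir_dd_spectrum(seed=config.seed, ratio=0.43092)
    dd = degree_of_deacetylation(spectrum)
    metrics = composite_metrics(8.0, 2.08, 25.74)
    return {
        "yield_percent": chitosan_yield(7.82, 100.0),
        "degree_of_deacetylation": dd.dd,
        "encapsulation_efficiency": metrics.ee,
        "loading_capacity": metrics.lc,
    }


_STAGE_FUNCS = {
    "fame": _stage_fame,
    "ferment": _stage_ferment,
    "pigment": _stage_pigment,
    "chitosan": _stage_chitosan,
}


def run_pipeline(config: RunConfig, dry_run: bool = False) -> dict:
    """Execute the selected stages in order and write JSON + markdown reports.

    With ``dry_run=True`` only the execution plan is returned; nothing is
    computed or written. Stage failures re-raise as :class:`PipelineError`
    with the stage named.
    """
    if dry_run:
        return {
            "plan": [
                {"stage": s, "input": config.inputs.get(s, "<packaged fixture>")}
                for s in config.stages
            ]
        }
    results: dict[str, Any] = {}
    for stage in config.stages:
        try:
            results[stage] = _STAGE_FUNCS[stage](config)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    echo = {
        "stages": config.stages,
        "inputs": config.inputs,
        "params": config.params,
        "defaults": {"sn_constant": 560.0, "mixing": "linear", "policy": "homolog"},
    }
    write_report(results, out / "report.json", "json", config_echo=echo, seed=config.seed)
    md_results = dict(results)
    if "fame" in md_results:
        fame_res = md_results.pop("fame")
        md_results = {"fuel_properties": fame_res["fuel_properties"], **md_results}
    write_report(md_results, out / "report.md", "markdown", config_echo=echo, seed=config.seed)
    return results
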