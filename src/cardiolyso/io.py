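"""Configuration files, result tables, and reproducibility manifests.

Run configuration is YAML; tabular results (population factors, biomarkers,
classifications) are CSV via pandas; each output directory carries a JSON
manifest with the seed, protocol, parameter scalings, solver settings and
package version, sufficient to re-run the experiment bit-compatibly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import CellParameters, STATE_NAMES
from .protocols import PROTOCOL_NAMES

__all__ = ["RunConfig", "load_config", "save_config", "write_manifest",
           "write_trace", "write_population_table", "write_biomarker_table",
           "read_biomarker_table", "lysosome_params_to_yaml",
           "lysosome_params_from_yaml"]

TRACE_COLUMNS = ("time", "V", "C_j", "C_sl", "C_i", "C_sr", "C_ls",
                 "J_SERCA", "J_RyR", "J_ls_up", "J_ls_rel", "ryr_po")


@dataclass
class RunConfig:
    """Configuration of one CLI run; round-trips losslessly through YAML."""

    protocol: str = "CTRL"
    ko: bool = False
    uptake_block: bool = False
    release_block: bool = False
    ncx3: bool = False
    seed: int = 0
    n_models: int = 1000
    preset: str = "full"          # "full" (150 beats) | "reduced" (100 beats)
    n_beats: int | None = None    # explicit override of beats per run
    outdir: str = "results"
    rtol: float = 1e-6
    parameter_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.protocol.upper() not in PROTOCOL_NAMES:
            raise ValueError(
                f"unknown protocol {self.protocol!r}; valid: {', '.join(PROTOCOL_NAMES)}")
        if self.preset not in ("full", "reduced"):
            raise ValueError("preset must be 'full' or 'reduced'")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def beats(self) -> int:
        if self.n_beats is not None:
            return int(self.n_beats)
        return 150 if self.preset == "full" else 100

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return RunConfig.from_dict(data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def build_parameters(config: RunConfig) -> CellParameters:
    params = CellParameters()
    for key, value in config.parameter_overrides.items():
        if key.startswith("lysosome."):
            setattr(params.lysosome, key.split(".", 1)[1], value)
        else:
            setattr(params, key, value)
    return params


def write_manifest(outdir, config: RunConfig | None = None, **extra) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"cardiolyso_version": __version__}
    if config is not None:
        manifest["config"] = config.to_dict()
    manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_trace(path, result) -> Path:
    """Write a simulation's recorded window as a columnar CSV."""
    data = {"time": result.t}
    for name in ("V", "C_j", "C_sl", "C_i", "C_sr", "C_ls"):
        data[name] = result.trace(name)
    for name in ("J_SERCA", "J_RyR", "J_ls_up", "J_ls_rel", "ryr_po"):
        data[name] = result.fluxes[name]
    df = pd.DataFrame(data, columns=list(TRACE_COLUMNS))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_population_table(path, population, calibration=None) -> Path:
    from .population import FACTOR_NAMES
    rows = []
    for i, member in enumerate(population):
        row = {"model_id": i, **member.as_dict()}
        if calibration is not None:
            if i in calibration.accepted:
                row["accepted"], row["reason"] = True, ""
            elif i in calibration.failed:
                row["accepted"], row["reason"] = False, "solver_failure"
            else:
                row["accepted"] = False
                row["reason"] = f"event_in_{calibration.rejected.get(i, 'unknown')}"
        rows.append(row)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


_BIOMARKER_FIELDS = ("amp_ci", "amp_cls", "amp_serca", "amp_ryr",
                     "diastolic_ci", "systolic_ci", "t50_ms", "ryr_po_peak")


def write_biomarker_table(path, runs: dict) -> Path:
    """Persist ModelRun analyses: runs maps (model_id, protocol, arm) -> ModelRun."""
    rows = []
    for (model_id, protocol, arm), run in runs.items():
        row = {"model_id": model_id, "protocol": protocol, "arm": arm,
               "status": run.status, "n_events": run.n_events,
               "ambiguous": run.ambiguous}
        for f in _BIOMARKER_FIELDS:
            row[f] = getattr(run.biomarkers, f, np.nan) if run.biomarkers else np.nan
        rows.append(row)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_biomarker_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"model_id", "protocol", "arm", "status", "n_events"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"biomarker table missing columns: {sorted(missing)}")
    return df


def lysosome_params_to_yaml(params, path) -> None:
    """Write the lysosomal parameter set as a commented key-value file."""
    from .lysosome import LysosomeParams
    lines = ["# Lysosomal compartment parameters",
             "# rates in 1/ms, diffusion in pL/ms, volume in pL, NAADP in nM"]
    for f in dataclasses.fields(LysosomeParams):
        lines.append(f"{f.name}: {getattr(params, f.name)}")
    Path(path).write_text("\n".join(lines) + "\n")


def lysosome_params_from_yaml(path):
    from .lysosome import LysosomeParams
    data = yaml.safe_load(Path(path).read_text())
    for key, value in data.items():
        if key not in ("release_blocked", "uptake_blocked"):
            data[key] = float(value)  # YAML 1.1 reads bare "1e-06" as a string
    return LysosomeParams(**data)
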