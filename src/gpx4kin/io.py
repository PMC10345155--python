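"""CSV/YAML interchange for traces, conditions and parameters.

A trace travels as a two-column CSV (``time_s,a340``) next to a YAML
sidecar ``<stem>.conditions.yaml`` holding the reaction conditions and,
for synthetic data, the generating kinetic parameters (the "truth
file") so recovery can be checked downstream.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .model_core import AbsorbanceTrace, KineticParameters, ReactionConditions

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "conditions_to_dict",
    "conditions_from_dict",
    "params_to_dict",
    "params_from_dict",
]


def conditions_to_dict(cond: ReactionConditions) -> dict:
    return {k: (float(v) if isinstance(v, (int, float)) and not isinstance(v, bool) else v)
            for k, v in asdict(cond).items()}


def conditions_from_dict(data: dict) -> ReactionConditions:
    return ReactionConditions(**data)


def params_to_dict(params: KineticParameters) -> dict:
    return {k: float(v) for k, v in asdict(params).items()}


def params_from_dict(data: dict) -> KineticParameters:
    return KineticParameters(**data)


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix("").with_suffix(".conditions.yaml")


def write_trace_csv(
    trace: AbsorbanceTrace,
    csv_path: str | Path,
    truth_params: KineticParameters | None = None,
) -> Path:
    """Write a trace as ``time_s,a340`` CSV with a YAML conditions sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": trace.times, "a340": trace.a340}).to_csv(
        csv_path, index=False
    )
    sidecar: dict = {
        "conditions": conditions_to_dict(trace.conditions),
        "label": trace.label,
        "is_blank": bool(trace.is_blank),
    }
    if truth_params is not None:
        sidecar["truth_params"] = params_to_dict(truth_params)
    with open(_sidecar_path(csv_path), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return csv_path


def read_trace_csv(
    csv_path: str | Path,
) -> tuple[AbsorbanceTrace, KineticParameters | None]:
    """Read a trace CSV and its sidecar; returns (trace, truth_params or None)."""
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    if not {"time_s", "a340"} <= set(frame.columns):
        raise ConfigError(f"{csv_path} lacks the required time_s,a340 columns")
    sidecar_file = _sidecar_path(csv_path)
    if not sidecar_file.exists():
        raise ConfigError(f"missing conditions sidecar {sidecar_file}")
    with open(sidecar_file) as fh:
        sidecar = yaml.safe_load(fh)
    trace = AbsorbanceTrace(
        times=np.asarray(frame["time_s"], dtype=float),
        a340=np.asarray(frame["a340"], dtype=float),
        conditions=conditions_from_dict(sidecar["conditions"]),
        label=sidecar.get("label", ""),
        is_blank=bool(sidecar.get("is_blank", False)),
    )
    truth = sidecar.get("truth_params")
    return trace, (params_from_dict(truth) if truth else None)
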