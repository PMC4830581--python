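"""Run configuration, manifests, and report serialization."""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib import metadata
from pathlib import Path

import yaml

from .decision import DecisionConfig
from .planner import PlanConfig
from .priors import DEFAULT_IDENTITY, DEFAULT_MU_VARIANT

__all__ = ["load_config", "save_config", "RunManifest", "write_report"]

_PLAN_KEYS = {f.name for f in dataclasses.fields(PlanConfig)}
_DECISION_KEYS = {f.name for f in dataclasses.fields(DecisionConfig)} - {"plan"}


def load_config(path: str | Path) -> DecisionConfig:
    """Load a YAML or JSON run configuration.

    Unset fields fall back to the reference-table defaults (K=100, R=10,
    Theta=0.8, T_max=12, G_res=30%).  Unknown keys and out-of-range values
    raise ``ValueError``.
    """
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(data)}")
    unknown = set(data) - _DECISION_KEYS - {"plan"}
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    plan_data = data.pop("plan", {}) or {}
    unknown_plan = set(plan_data) - _PLAN_KEYS
    if unknown_plan:
        raise ValueError(f"unknown plan keys: {sorted(unknown_plan)}")
    return DecisionConfig(plan=PlanConfig(**plan_data), **data)


def save_config(cfg: DecisionConfig, path: str | Path) -> None:
    path = Path(path)
    data = asdict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    command: str
    seed: int
    config: dict
    mu_variant: str = DEFAULT_MU_VARIANT
    identity_convention: str = DEFAULT_IDENTITY
    package_version: str = field(
        default_factory=lambda: _version_or("hanoiplan", "unknown")
    )
    python_version: str = field(default_factory=platform.python_version)
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        )


def _version_or(name: str, fallback: str) -> str:
    try:
        return metadata.version(name)
    except metadata.PackageNotFoundError:
        return fallback


def write_report(report, out_dir: str | Path, manifest: RunManifest | None = None):
    """Write an :class:`~hanoiplan.experiments.ExperimentReport` to disk.

    Produces ``runs.csv`` (one row per run), ``report.json`` (aggregates),
    one CSV per auxiliary series, and optionally the run manifest.  Output
    is deterministic: rows and keys are written in a fixed order.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    runs_path = out / "runs.csv"
    report.runs.to_csv(runs_path, index=False)
    written.append(runs_path.name)

    agg = {str(k): _jsonable(v) for k, v in sorted(report.aggregates.items(), key=lambda kv: str(kv[0]))}
    report_path = out / "report.json"
    report_path.write_text(
        json.dumps({"experiment": report.experiment, "aggregates": agg},
                   indent=2, sort_keys=True) + "\n"
    )
    written.append(report_path.name)

    for name, frame in sorted(report.series.items()):
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        written.append(p.name)

    if manifest is not None:
        manifest.outputs = written
        manifest.write(out / "manifest.json")
        written.append("manifest.json")
    return [out / w for w in written]


def _jsonable(v):
    if isinstance(v, dict):
        return {str(k): _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if hasattr(v, "item"):
        return v.item()
    return v
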