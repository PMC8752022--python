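"""File I/O: area tables, policies, scenarios, model sets, run manifests.

All tabular formats are plain CSV with dot decimal separators; thousands
separators are rejected (a converter utility, :func:`strip_thousands`,
handles human-formatted tables). Policies, scenarios and generator
parameters are JSON or YAML (chosen by file extension).
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .basefunc import BaseFunctionModel
from .causal import Intervention, Policy
from .ecosystem import COLUMNS, AreaRecord, EcosystemTable
from .scenarios import Scenario, ScenarioSet

__all__ = [
    "read_ecosystem",
    "write_ecosystem",
    "strip_thousands",
    "read_policy",
    "write_policy",
    "read_scenarios",
    "write_scenarios",
    "read_models",
    "write_models",
    "RunManifest",
]


def _parse_number(token: str, line_no: int, column: str) -> float:
    token = token.strip()
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"line {line_no}: non-numeric value {token!r} in column {column!r} "
            "(thousands separators are not accepted; see strip_thousands)"
        ) from None


def read_ecosystem(path: str | Path, label: str | None = None) -> EcosystemTable:
    """Read an area table CSV with strict, locale-fixed numeric parsing."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    missing = set(COLUMNS) - set(header)
    if missing:
        raise ValueError(f"{path}: missing columns: {sorted(missing)}")
    idx = {c: header.index(c) for c in COLUMNS}
    records: list[AreaRecord] = []
    seen: dict[str, int] = {}
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != len(header):
            raise ValueError(f"{path}: line {line_no}: expected {len(header)} fields, got {len(cells)}")
        area_id = cells[idx["area_id"]].strip()
        if area_id in seen:
            raise ValueError(
                f"{path}: duplicate area_id {area_id!r} on lines {seen[area_id]} and {line_no}"
            )
        seen[area_id] = line_no
        kwargs: dict[str, Any] = {"area_id": area_id}
        for col in COLUMNS[1:]:
            kwargs[col] = _parse_number(cells[idx[col]], line_no, col)
        records.append(AreaRecord(**kwargs))
    return EcosystemTable(records, label=label or path.stem)


def write_ecosystem(table: EcosystemTable, path: str | Path) -> None:
    """Write the area table as CSV at full float precision (lossless round-trip)."""
    frame = table.to_frame()
    with open(path, "w") as fh:
        fh.write(",".join(COLUMNS) + "\n")
        for _, row in frame.iterrows():
            fh.write(",".join([str(row["area_id"])] + [repr(float(row[c])) for c in COLUMNS[1:]]) + "\n")


def strip_thousands(text: str) -> str:
    """Convert a human-formatted table: drop thousands separators like 21,593.

    A comma is treated as a separator when it sits between digits with exactly
    three digits following before the next non-digit; this converts quoted
    cells such as ``"21,593"`` into ``21593``.
    """
    import re

    def fix_cell(m: "re.Match[str]") -> str:
        return m.group(0).replace(",", "").strip('"')

    return re.sub(r'"\d{1,3}(?:,\d{3})+(?:\.\d+)?"', fix_cell, text)


# --- policies ------------------------------------------------------------

def _load_structured(path: Path) -> Any:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _dump_structured(obj: Any, path: Path) -> None:
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(obj, sort_keys=False))
    else:
        path.write_text(json.dumps(obj, indent=2) + "\n")


def read_policy(path: str | Path) -> Policy:
    raw = _load_structured(Path(path))
    try:
        interventions = tuple(
            Intervention(e["area_id"], e["variable"], float(e["delta"]))
            for e in raw["interventions"]
        )
        return Policy(raw.get("label", Path(path).stem), interventions)
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: malformed policy file ({exc})") from exc


def write_policy(policy: Policy, path: str | Path) -> None:
    _dump_structured(
        {
            "label": policy.label,
            "interventions": [dataclasses.asdict(i) for i in policy.interventions],
        },
        Path(path),
    )


# --- scenarios -----------------------------------------------------------

def read_scenarios(path: str | Path) -> ScenarioSet:
    raw = _load_structured(Path(path))
    try:
        return ScenarioSet(
            [Scenario(e["id"], tuple(e["inputs"]), tuple(e["outputs"])) for e in raw["scenarios"]]
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: malformed scenario file ({exc})") from exc


def write_scenarios(scenarios: ScenarioSet, path: str | Path) -> None:
    _dump_structured(
        {
            "scenarios": [
                {"id": s.id, "inputs": list(s.inputs), "outputs": list(s.outputs)}
                for s in scenarios
            ]
        },
        Path(path),
    )


# --- fitted model sets ---------------------------------------------------

def write_models(models: dict[str, BaseFunctionModel], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({k: m.to_dict() for k, m in models.items()}, indent=2) + "\n"
    )


def read_models(path: str | Path) -> dict[str, BaseFunctionModel]:
    raw = json.loads(Path(path).read_text())
    return {k: BaseFunctionModel.from_dict(v) for k, v in raw.items()}


# --- run manifest --------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit (except timestamps)."""

    seed: int
    config: dict[str, Any]
    input_digests: dict[str, str] = field(default_factory=dict)
    artifact_version: str = "0.1.0"
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.input_digests[p.name] = _digest(p)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
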