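"""File readers/writers and model-configuration handling.

Count tables travel as long-format CSV (``from,to,count``); model
configurations as YAML or JSON with keys ``states``, ``absorbing``,
``transitions``, ``merges`` and optional ``costs``/``utilities``/
``cycle_length``.  Reports are written as CSV (AIC rounded to 1 d.p., the
conventional presentation) and as JSON with full-precision numbers plus run
metadata (seed, package version, input hash) sufficient to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .likelihood import ComparisonTable, TransitionCountTable
from .structures import MergeSpec, StateSpace

__all__ = [
    "read_count_table",
    "write_count_table",
    "load_model_config",
    "dump_model_config",
    "write_report",
    "read_report_json",
]


def read_count_table(path: str | Path) -> TransitionCountTable:
    """Read a long-format transition count CSV with header ``from,to,count``.

    Duplicate (from, to) rows are summed; counts must be non-negative
    integers.
    """
    frame = pd.read_csv(path, dtype={"from": str, "to": str})
    required = ["from", "to", "count"]
    if list(frame.columns[:3]) != required:
        raise ValueError(
            f"malformed header {list(frame.columns)}; expected {required}"
        )
    if frame.empty:
        return TransitionCountTable({})
    bad = frame["count"].astype(float) != frame["count"].astype(float).round()
    if bad.any() or (frame["count"].astype(float) < 0).any():
        raise ValueError("counts must be non-negative integers")
    return TransitionCountTable.from_frame(frame)


def write_count_table(table: TransitionCountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def load_model_config(path: str | Path) -> dict[str, Any]:
    """Load a model configuration (YAML or JSON) into validated objects.

    Returns a dict with ``space`` (StateSpace), ``transitions`` (set of
    allowed pairs), ``merges`` (name -> MergeSpec), and any ``costs``,
    ``utilities``, ``cycle_length`` entries found.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping) or "states" not in raw:
        raise ValueError("model config must be a mapping with a 'states' list")
    space = StateSpace(raw["states"], raw.get("absorbing", ()))
    transitions = {tuple(t) for t in raw.get("transitions", [])}
    for o, d in transitions:
        if o not in space or d not in space:
            raise ValueError(f"transition ({o}, {d}) references unknown states")
    merges = {
        name: MergeSpec(groups) for name, groups in raw.get("merges", {}).items()
    }
    for m in merges.values():
        m.validate_against(space)
    out = {"space": space, "transitions": transitions, "merges": merges}
    for key in ("costs", "utilities", "cycle_length",
                "transition_probabilities", "strategies"):
        if key in raw:
            out[key] = raw[key]
    return out


def dump_model_config(config: Mapping[str, Any], path: str | Path) -> None:
    """Write a model configuration back to YAML/JSON, loss-lessly."""
    space: StateSpace = config["space"]
    raw: dict[str, Any] = {
        "states": list(space.states),
        "absorbing": sorted(space.absorbing),
        "transitions": sorted([list(t) for t in config.get("transitions", set())]),
        "merges": {
            name: {label: sorted(members) for label, members in spec.groups}
            for name, spec in config.get("merges", {}).items()
        },
    }
    for key in ("costs", "utilities", "cycle_length",
                "transition_probabilities", "strategies"):
        if key in config:
            raw[key] = config[key]
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(raw, indent=2))
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=False))


def _metadata(seed: int | None, inputs: Mapping[str, Any]) -> dict[str, Any]:
    digest = hashlib.sha256(
        json.dumps(inputs, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {"seed": seed, "statemerge_version": __version__, "config_hash": digest}


def write_report(
    result: ComparisonTable | Mapping[str, Any],
    path: str | Path,
    fmt: str = "csv",
    seed: int | None = None,
    inputs: Mapping[str, Any] | None = None,
) -> None:
    """Write a comparison table or VOI summary to ``path``.

    ``fmt`` is "csv" (AIC columns rounded to 1 d.p.) or "json"
    (full-precision values plus run metadata).
    """
    path = Path(path)
    meta = _metadata(seed, inputs or {})
    if fmt == "csv":
        if isinstance(result, ComparisonTable):
            result.rendered().to_csv(path, index=False)
        else:
            pd.DataFrame([dict(result)]).to_csv(path, index=False)
    elif fmt == "json":
        if isinstance(result, ComparisonTable):
            payload = {"rows": result.frame.to_dict(orient="records")}
        else:
            payload = {"summary": dict(result)}
        payload["metadata"] = meta
        path.write_text(json.dumps(payload, indent=2, default=float))
    else:
        raise ValueError(f"unsupported format {fmt!r}; use 'csv' or 'json'")


def read_report_json(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
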