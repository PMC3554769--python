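"""Configuration files, bundled defaults and tabular output.

Parameter and primitives files are flat JSON (YAML also accepted on read);
canonical serialization is JSON so save/load round trips are byte-stable.
Tables are written as RFC-4180 CSV preceded by a '#'-prefixed metadata header
(tool version, seed, parameter hash) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .calibration import CalibrationPrimitives
from .model import ModelDomainError, ParameterSet

__all__ = ["load_parameters", "save_parameters", "load_primitives",
           "save_primitives", "default_parameters", "default_primitives",
           "write_table", "read_table", "parameter_hash"]

_DATA = resources.files("emtmir") / "data"


def _load_document(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _dump_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_parameters(path: str | Path, strict: bool = False) -> ParameterSet:
    """Load and validate a ParameterSet file (JSON or YAML)."""
    doc = _load_document(path)
    return ParameterSet.from_dict(doc, strict=strict)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    _dump_json(params.to_dict(), path)


def load_primitives(path: str | Path) -> CalibrationPrimitives:
    return CalibrationPrimitives.from_dict(_load_document(path))


def save_primitives(prim: CalibrationPrimitives, path: str | Path) -> None:
    _dump_json(prim.to_dict(), path)


def default_primitives() -> CalibrationPrimitives:
    """The bundled calibration primitives (see docs/methods.md for provenance)."""
    with resources.as_file(_DATA / "primitives.json") as p:
        return load_primitives(p)


def default_parameters() -> ParameterSet:
    """The bundled calibrated parameter set (healthy-cell fixed point)."""
    with resources.as_file(_DATA / "parameters.json") as p:
        return load_parameters(p)


def parameter_hash(params: ParameterSet) -> str:
    """Short stable digest of a parameter set, for provenance headers."""
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_table(table: pd.DataFrame, path: str | Path,
                metadata: dict | None = None) -> None:
    """Write a DataFrame as CSV with a '#'-prefixed metadata header block."""
    if table is None or len(table) == 0:
        raise ModelDomainError("refusing to write an empty table")
    from . import __version__
    lines = [f"# emtmir version: {__version__}"]
    for k, v in (metadata or {}).items():
        lines.append(f"# {k}: {v}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        table.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (metadata lines skipped)."""
    return pd.read_csv(path, comment="#")
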