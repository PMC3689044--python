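"""CSV tables with metadata comments and JSON run sidecars."""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["SchemaError", "write_table", "read_table", "write_sidecar", "read_sidecar"]


class SchemaError(ValueError):
    """A table is missing a required column."""


def write_table(path, df: pd.DataFrame, metadata: dict | None = None) -> None:
    """Write a CSV with '#'-prefixed metadata comment lines.

    Floats are serialised with shortest round-trip repr (up to 17
    significant digits, '.0' kept on integral values) so
    read(write(x)) == x including dtypes.
    """
    path = Path(path)
    lines = []
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    csv = df.to_csv(index=False)
    path.write_text("\n".join(lines) + ("\n" if lines else "") + csv)


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV written by write_table, checking required columns."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in required or []:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    return df


def write_sidecar(path, params: dict, seed: int | None = None) -> None:
    """JSON sidecar recording parameters, seed, version and timestamp."""
    payload = {
        "params": params,
        "seed": seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
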