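"""Shared TSV/JSON I/O with provenance headers.

All tabular writers prepend a single ``#``-prefixed provenance line holding
the package version and the parameters that produced the file; readers skip
any leading ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__


def provenance_line(stage: str, params: Mapping[str, Any] | None = None) -> str:
    parts = [f"ribodwell={__version__}", f"stage={stage}"]
    if params:
        for k in sorted(params):
            parts.append(f"{k}={params[k]}")
    return "# " + " ".join(parts)


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    stage: str,
    params: Mapping[str, Any] | None = None,
    index: bool = False,
) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(stage, params) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_json(obj: Any, path: str | Path, stage: str, params: Mapping[str, Any] | None = None) -> None:
    payload = {"_provenance": provenance_line(stage, params), "data": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> Any:
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict) and "data" in payload and "_provenance" in payload:
        return payload["data"]
    return payload


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable short hash of a (nested, JSON-serializable) configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
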