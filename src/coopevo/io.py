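"""Result serialization and experiment manifests.

Every result table written to disk is accompanied by a JSON manifest that
records the parameters, grids, seeds, engine and software version that
produced it, so any CSV can be traced back to a fully specified,
re-runnable experiment.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .params import ModelParams
from .states import ENUMERATION_ORDER

__all__ = ["ExperimentManifest", "write_results", "read_results"]


@dataclass
class ExperimentManifest:
    """Provenance record tying a result file to parameters and seeds."""

    engine: str  # "exact" | "abm"
    params: dict[str, Any]
    grids: dict[str, list] = field(default_factory=dict)
    seeds: dict[str, Any] = field(default_factory=dict)
    extra: dict[str, Any] = field(default_factory=dict)
    version: str = __version__
    enumeration_order: str = ENUMERATION_ORDER
    created: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.datetime.now(datetime.timezone.utc).isoformat()
        if isinstance(self.params, ModelParams):
            self.params = self.params.to_dict()

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentManifest":
        return cls(**json.loads(text))


def write_results(
    table: pd.DataFrame, manifest: ExperimentManifest, path: str | Path
) -> tuple[Path, Path]:
    """Write a result CSV plus its JSON manifest sidecar.

    Numeric columns keep at least 12 significant digits (the full float64
    repr is written) so a read-back reproduces the in-memory values.
    Returns the (csv_path, manifest_path) pair.
    """
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    manifest_path = path.with_suffix(".manifest.json")
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(path, index=False, float_format="%.17g")
        manifest_path.write_text(manifest.to_json() + "\n")
    except OSError as err:
        raise OSError(f"failed writing results to {path}: {err}") from err
    return path, manifest_path


def read_results(path: str | Path) -> tuple[pd.DataFrame, ExperimentManifest]:
    """Read back a (CSV, manifest) pair written by :func:`write_results`."""
    path = Path(path)
    table = pd.read_csv(path)
    manifest = ExperimentManifest.from_json(path.with_suffix(".manifest.json").read_text())
    return table, manifest
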