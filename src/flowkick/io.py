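"""Configuration, serialization and run-metadata plumbing for the CLI.

All artifacts are diff-able text: CSV with a header row and 17
significant digits for floats, JSON for nested structures.  A run's
metadata echo (config, versions, tolerances) makes it reproducible.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .model import DisturbanceRegime, ModelParams

__all__ = [
    "RunConfig",
    "load_config",
    "write_csv",
    "read_csv",
    "write_json",
    "run_metadata",
]

FLOAT_FMT = "%.17g"


@dataclass
class RunConfig:
    """Validated run configuration.

    Nested config-file keys (``model.alpha``, ``regime.k1``,
    ``solver.rtol`` ...) are flattened into the dataclass; type invariants
    are enforced by the ModelParams/DisturbanceRegime constructors before
    any computation runs.
    """

    model: ModelParams = field(default_factory=ModelParams)
    regime: DisturbanceRegime = None
    solver: dict = field(default_factory=lambda: {"rtol": 1e-10, "atol": 1e-10})

    def to_dict(self):
        return {
            "model": asdict(self.model),
            "regime": asdict(self.regime) if self.regime else None,
            "solver": dict(self.solver),
        }


def load_config(path) -> RunConfig:
    """Read a YAML or TOML config with model/regime/solver sections."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        raw = tomllib.loads(text)
    else:
        import yaml

        raw = yaml.safe_load(text)
    raw = raw or {}
    model = ModelParams(**raw.get("model", {}))
    regime = DisturbanceRegime(**raw["regime"]) if "regime" in raw else None
    solver = {"rtol": 1e-10, "atol": 1e-10}
    solver.update(raw.get("solver", {}))
    return RunConfig(model=model, regime=regime, solver=solver)


def _fmt(v):
    if isinstance(v, (float, np.floating)):
        return FLOAT_FMT % v
    return str(v)


def write_csv(path, columns, rows):
    """Write rows (sequences matching ``columns``) as headered CSV with
    17-significant-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(",".join(columns) + "\n")
        for row in rows:
            fh.write(",".join(_fmt(v) for v in row) + "\n")
    return path


def read_csv(path):
    """Read a CSV written by :func:`write_csv` back into (columns, ndarray
    of objects with floats where possible)."""
    import pandas as pd

    df = pd.read_csv(path)
    return list(df.columns), df


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, complex):
            return {"re": obj.real, "im": obj.imag}
        return super().default(obj)


def write_json(path, payload):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")
    return path


def run_metadata(config: RunConfig, command: str, extra: dict = None):
    """Reproducibility echo written alongside every CLI artifact."""
    from . import __version__

    meta = {
        "command": command,
        "config": config.to_dict(),
        "package_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
    }
    if extra:
        meta.update(extra)
    return meta
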