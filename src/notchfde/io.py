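"""Configuration loading, result serialization and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import yaml

from .lattice import LatticeScenario, PhenotypeMap
from .model import ModelParameters
from .solver import SolverConfig, Trajectory

__all__ = [
    "ConfigError",
    "load_config",
    "scenario_from_config",
    "write_trajectory_csv",
    "write_trajectory_npy",
    "write_json",
    "write_heatmap_png",
    "write_manifest",
]


class ConfigError(ValueError):
    """A config file violates the expected schema."""


#: allowed keys per config section
_SCHEMA = {
    "preset": str,
    "params": set(ModelParameters().as_dict()),
    "solver": {"h", "t_end", "memory_window", "record_stride"},
    "lattice": {"rows", "cols", "lambda_rows", "horizontal_periodic"},
    "morris": {"R", "seed", "range_fraction", "delta_fraction"},
    "sweep": {"parameter", "values"},
    "alphas": list,
    "thresholds": list,
    "seed": int,
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML/JSON config file and validate its keys.

    An empty (or absent) file yields all defaults; unknown keys raise
    :class:`ConfigError` naming the offending key.
    """
    if path is None:
        return {}
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    for key, value in data.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config key: {key!r}")
        allowed = _SCHEMA[key]
        if isinstance(allowed, set):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {key!r} must be a mapping")
            for sub in value:
                if sub not in allowed:
                    raise ConfigError(f"unknown config key: {key}.{sub!r}")
    return data


def scenario_from_config(config: dict):
    """Resolve a config dict into (params, solver, lattice-or-None).

    Values given in the config override the preset (if any) and the
    defaults; parameter validation happens in the dataclass constructors.
    """
    from .presets import get_preset

    params = ModelParameters()
    solver = None
    lattice = None
    if "preset" in config:
        preset = get_preset(config["preset"])
        params, solver = preset.params, preset.solver
        lattice = preset.lattice
    if "params" in config:
        params = params.replace(**config["params"])
    if "solver" in config:
        base = solver or SolverConfig()
        solver = SolverConfig(**{**asdict(base), **config["solver"]})
    if "lattice" in config:
        spec = dict(config["lattice"])
        if "lambda_rows" in spec:
            spec["lambda_rows"] = tuple(float(v) for v in spec["lambda_rows"])
        base_kwargs = {} if lattice is None else {
            "rows": lattice.rows,
            "cols": lattice.cols,
            "lambda_rows": lattice.lambda_rows,
            "horizontal_periodic": lattice.horizontal_periodic,
        }
        base_kwargs.update(spec)
        lattice = LatticeScenario(
            params=params,
            solver=solver or SolverConfig(h=0.5),
            **base_kwargs,
        )
    elif lattice is not None:
        lattice = lattice.replace(params=params, solver=solver or lattice.solver)
    return params, solver or SolverConfig(), lattice


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(payload, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
    return path


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    """Tidy CSV with columns time, cell, D, N, A."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # default float formatting is the shortest round-trip repr, i.e. exact
    traj.to_frame().to_csv(path, index=False)
    return path


def read_trajectory_csv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, float_precision="round_trip")


def write_trajectory_npy(traj: Trajectory, path: str | Path) -> Path:
    """Raw array dump (n_times, n_cells, 3) for fast reload."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, traj.states)
    return path


def write_heatmap_png(
    matrix: np.ndarray, path: str | Path, vmax: float | None = None
) -> Path:
    """Blue-intensity heatmap of a Notch matrix (darker = more Notch)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mat = np.asarray(matrix, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 3))
    im = ax.imshow(mat, cmap="Blues", vmin=0.0, vmax=vmax, aspect="equal")
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    fig.colorbar(im, ax=ax, label="Notch level")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _package_version() -> str:
    try:
        return version("notchfde")
    except PackageNotFoundError:  # pragma: no cover - editable odd cases
        return "unknown"


def write_manifest(
    resolved_config: dict, out_dir: str | Path, seed: int | None = None
) -> Path:
    """JSON manifest echoing the fully resolved configuration.

    Includes the package version and a SHA-256 hash of the canonicalised
    configuration so that two runs can be compared byte-for-byte.
    """
    payload = _jsonable(resolved_config)
    blob = json.dumps(payload, sort_keys=True).encode()
    manifest = {
        "config": payload,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "package_version": _package_version(),
    }
    return write_json(manifest, Path(out_dir) / "manifest.json")
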