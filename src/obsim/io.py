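"""Configuration loading, result serialization, and deterministic fixtures.

A run configuration is one YAML/JSON document with three sections:
``model`` (flat :class:`~obsim.params.ModelParams` mapping), ``protocol``
(name + options) and top-level ``seed`` / ``out``.  Unknown keys anywhere
are an error so that typos never silently fall back to defaults.

Results are written as human-inspectable CSV time series plus an HDF5
snapshot holding the final connectivity as sparse triplets, and a
``run.json`` echo of the fully resolved configuration that suffices to
reproduce every file bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .experiments import ExperimentResult, ProtocolSpec
from .network import SynapseMatrix
from .params import ModelParams

__all__ = ["RunConfig", "load_config", "save_result", "load_snapshot",
           "generate_fixture", "FIXTURE_NAMES"]


@dataclasses.dataclass
class RunConfig:
    """A fully validated run description."""

    params: ModelParams
    protocol: ProtocolSpec
    seed: int = 0
    out: str | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.params.to_dict(),
            "protocol": {"name": self.protocol.name,
                         "options": dict(self.protocol.options)},
            "seed": self.seed,
            "out": self.out,
        }


_TOP_KEYS = {"model", "protocol", "seed", "out"}


def _config_from_mapping(doc: dict, source: str = "<config>") -> RunConfig:
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError(f"{source}: configuration must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise KeyError(f"{source}: unknown top-level key(s) {sorted(unknown)}")
    try:
        params = ModelParams.from_dict(doc.get("model", {}) or {})
    except (KeyError, ValueError) as err:
        raise type(err)(f"{source}: in section 'model': {err}") from err
    proto_doc = doc.get("protocol", {}) or {}
    unknown = set(proto_doc) - {"name", "options"}
    if unknown:
        raise KeyError(f"{source}: unknown protocol key(s) {sorted(unknown)}")
    protocol = ProtocolSpec(proto_doc.get("name", "perceptual_learning"),
                            dict(proto_doc.get("options", {}) or {}))
    seed = doc.get("seed", 0)
    if not isinstance(seed, int):
        raise ValueError(f"{source}: seed must be an integer")
    return RunConfig(params=params, protocol=protocol, seed=seed,
                     out=doc.get("out"))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _config_from_mapping(doc, source=str(path))


def save_result(result: ExperimentResult, out_dir: str | Path) -> dict[str, Path]:
    """Write CSV tables, HDF5 snapshot and the configuration echo.

    Returns the mapping of logical names to written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["memory_trace"] = out / "memory_trace.csv"
    result.trace.to_csv(files["memory_trace"], index=False)
    files["census"] = out / "census.csv"
    result.census.to_csv(files["census"], index=False)

    files["run"] = out / "run.json"
    echo = {
        "model": result.params.to_dict(),
        "protocol": ({"name": result.protocol.name,
                      "options": result.protocol.options}
                     if result.protocol else None),
        "seed": result.seed,
        "extras": _jsonable(result.extras),
        "runtime_s": result.runtime_s,
    }
    with open(files["run"], "w", encoding="utf-8") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True)

    if result.synapses is not None:
        files["snapshots"] = out / "snapshots.h5"
        with h5py.File(files["snapshots"], "w") as h5:
            grp = h5.create_group("final")
            _write_sparse(grp, "state", result.synapses.state)
            _write_sparse(grp, "field_mask",
                          result.synapses.field_mask.astype(np.int8))
            grp.attrs["n_mc"] = result.synapses.n_mc
            grp.attrs["n_gc"] = result.synapses.n_gc
            if result.state is not None:
                grp.create_dataset("gc_birthdate", data=result.state.gc_birthdate)
                grp.create_dataset("gc_id", data=result.state.gc_id)
    return files


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_sparse(grp: h5py.Group, name: str, matrix: np.ndarray) -> None:
    """Store a small integer matrix as (row, col, value) triplets."""
    rows, cols = np.nonzero(matrix)
    sub = grp.create_group(name)
    sub.create_dataset("row", data=rows.astype(np.int32))
    sub.create_dataset("col", data=cols.astype(np.int32))
    sub.create_dataset("value", data=matrix[rows, cols])
    sub.attrs["shape"] = matrix.shape


def load_snapshot(path: str | Path, group: str = "final") -> SynapseMatrix:
    """Reconstruct a :class:`SynapseMatrix` from an HDF5 snapshot."""
    with h5py.File(path, "r") as h5:
        grp = h5[group]
        state = _read_sparse(grp["state"]).astype(np.int8)
        mask = _read_sparse(grp["field_mask"]).astype(bool)
    return SynapseMatrix(mask, state)


def _read_sparse(sub: h5py.Group) -> np.ndarray:
    shape = tuple(sub.attrs["shape"])
    out = np.zeros(shape, dtype=np.asarray(sub["value"]).dtype)
    out[np.asarray(sub["row"]), np.asarray(sub["col"])] = np.asarray(sub["value"])
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("tiny_network", "planted_clusters", "shuffle_enum")


def generate_fixture(name: str, seed: int = 0) -> dict:
    """Small deterministic bundles used by tests and demos.

    * ``tiny_network`` - a 6-MC / 8-GC network with random consolidated
      synapses, its excitability vector and a stimulus.
    * ``planted_clusters`` - a binary connectivity matrix with two planted
      blocks (within-block density 0.8, background 0.05) plus ground-truth
      labels.
    * ``shuffle_enum`` - an instance small enough (4 MCs, degree 2) to
      enumerate all reshuffled connectivities exhaustively.
    """
    rng = np.random.default_rng(seed)
    if name == "tiny_network":
        n_mc, n_gc = 6, 8
        mask = np.zeros((n_mc, n_gc), dtype=bool)
        state = np.zeros((n_mc, n_gc), dtype=np.int8)
        for j in range(n_gc):
            fld = rng.choice(n_mc, size=4, replace=False)
            mask[fld, j] = True
            state[rng.choice(fld, size=2, replace=False), j] = 2
        return {"synapses": SynapseMatrix(mask, state),
                "excitability": np.ones(n_gc),
                "stimulus": rng.uniform(0.1, 1.0, size=n_mc)}
    if name == "planted_clusters":
        n_mc, n_per = 40, 30
        block1 = (rng.random((n_mc, n_per)) < 0.05).astype(float)
        block1[:12] = (rng.random((12, n_per)) < 0.8).astype(float)
        block2 = (rng.random((n_mc, n_per)) < 0.05).astype(float)
        weights = np.concatenate([block1, block2], axis=1)
        labels = np.array([1] * n_per + [0] * n_per)
        return {"weights": weights, "labels": labels,
                "responsive_mc": (np.arange(n_mc) < 12).astype(float)}
    if name == "shuffle_enum":
        n_mc = 4
        mbar = np.array([1.0, 0.0, 0.0, 0.0])
        w = np.zeros((n_mc, 1))
        w[[0, 1], 0] = 1.0  # degree 2
        return {"weights": w, "mbar": mbar, "degree": 2}
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
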