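"""Plain-text file formats with JSON metadata sidecars.

Matrices (rasters, traces, adjacency, weights) are stored as tab-delimited
text — rows are cells — so every artifact can be inspected and consumed
without this package.  Each matrix file ``X.tsv`` carries a sidecar
``X.meta.json`` with the acquisition/provenance metadata needed to rebuild
the in-memory object exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .metrics import NetworkMetrics
from .network import EffectiveNetwork
from .raster import CalciumTraces, SpikeRaster
from .simulate import GroundTruthNetwork

__all__ = [
    "ParseError",
    "read_raster",
    "write_raster",
    "read_traces",
    "write_traces",
    "read_network",
    "write_network",
    "read_ground_truth",
    "write_ground_truth",
    "read_metrics",
    "write_metrics",
]


class ParseError(ValueError):
    """A file on disk does not conform to the expected format."""


def _sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def _load_matrix(path: Path, dtype=float) -> np.ndarray:
    try:
        mat = np.loadtxt(path, delimiter="\t", dtype=dtype, ndmin=2)
    except ValueError as exc:  # np.loadtxt reports the offending line in its message
        raise ParseError(f"{path}: {exc}") from exc
    return mat


def _save_matrix(path: Path, mat: np.ndarray, fmt: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, mat, delimiter="\t", fmt=fmt)


def _read_meta(path: Path) -> dict:
    sidecar = _sidecar(path)
    if not sidecar.exists():
        return {}
    return json.loads(sidecar.read_text())


def _write_meta(path: Path, meta: dict) -> None:
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def write_raster(raster: SpikeRaster, path: str | Path, **extra_meta) -> Path:
    path = Path(path)
    _save_matrix(path, raster.spikes, fmt="%d")
    _write_meta(
        path,
        {"frame_rate": raster.frame_rate, "duration_s": raster.duration_s, **extra_meta},
    )
    return path


def read_raster(path: str | Path) -> SpikeRaster:
    path = Path(path)
    mat = _load_matrix(path, dtype=int)
    if not np.isin(mat, [0, 1]).all():
        raise ParseError(f"{path}: raster entries must be 0 or 1")
    meta = _read_meta(path)
    return SpikeRaster(
        mat,
        frame_rate=meta.get("frame_rate", SpikeRaster.frame_rate),
        duration_s=meta.get("duration_s"),
    )


def write_traces(traces: CalciumTraces, path: str | Path, **extra_meta) -> Path:
    path = Path(path)
    _save_matrix(path, traces.fluorescence, fmt="%.10g")
    _write_meta(
        path,
        {"frame_rate": traces.frame_rate, "is_relative": traces.is_relative, **extra_meta},
    )
    return path


def read_traces(path: str | Path) -> CalciumTraces:
    path = Path(path)
    mat = _load_matrix(path)
    meta = _read_meta(path)
    return CalciumTraces(
        mat,
        frame_rate=meta.get("frame_rate", CalciumTraces.frame_rate),
        is_relative=meta.get("is_relative", False),
    )


def write_network(net: EffectiveNetwork, prefix: str | Path, **extra_meta) -> Path:
    """Write adjacency + weights + provenance under ``<prefix>_*``."""
    prefix = Path(prefix)
    _save_matrix(prefix.with_name(prefix.name + "_adjacency.tsv"), net.adjacency, fmt="%d")
    _save_matrix(prefix.with_name(prefix.name + "_weights.tsv"), net.weights, fmt="%.10g")
    meta = {"provenance": net.provenance, **extra_meta}
    prefix.with_name(prefix.name + "_meta.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True, default=str) + "\n"
    )
    return prefix


def read_network(prefix: str | Path) -> EffectiveNetwork:
    prefix = Path(prefix)
    adj_path = prefix.with_name(prefix.name + "_adjacency.tsv")
    adjacency = _load_matrix(adj_path, dtype=int)
    if np.diag(adjacency).any():
        raise ParseError(f"{adj_path}: nonzero diagonal (self-connections are not allowed)")
    if not np.isin(adjacency, [0, 1]).all():
        raise ParseError(f"{adj_path}: adjacency entries must be 0 or 1")
    weights = _load_matrix(prefix.with_name(prefix.name + "_weights.tsv"))
    meta_path = prefix.with_name(prefix.name + "_meta.json")
    provenance = {}
    if meta_path.exists():
        provenance = json.loads(meta_path.read_text()).get("provenance", {})
    return EffectiveNetwork(adjacency, weights, provenance=provenance)


def write_ground_truth(net: GroundTruthNetwork, prefix: str | Path, **extra_meta) -> Path:
    prefix = Path(prefix)
    _save_matrix(prefix.with_name(prefix.name + "_adjacency.tsv"), net.adjacency, fmt="%d")
    _save_matrix(
        prefix.with_name(prefix.name + "_propagation.tsv"), net.propagation_prob, fmt="%.10g"
    )
    _save_matrix(
        prefix.with_name(prefix.name + "_modules.tsv"), net.module_labels[None, :], fmt="%d"
    )
    if extra_meta:
        prefix.with_name(prefix.name + "_meta.json").write_text(
            json.dumps(extra_meta, indent=1, sort_keys=True) + "\n"
        )
    return prefix


def read_ground_truth(prefix: str | Path) -> GroundTruthNetwork:
    prefix = Path(prefix)
    adjacency = _load_matrix(prefix.with_name(prefix.name + "_adjacency.tsv"), dtype=int)
    propagation = _load_matrix(prefix.with_name(prefix.name + "_propagation.tsv"))
    modules = _load_matrix(prefix.with_name(prefix.name + "_modules.tsv"), dtype=int).ravel()
    return GroundTruthNetwork(adjacency, propagation, modules)


def write_metrics(metrics: NetworkMetrics, path: str | Path, **extra_meta) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    record = metrics.to_dict()
    record.update(extra_meta)
    path.write_text(json.dumps(record, indent=1, sort_keys=True) + "\n")
    return path


def read_metrics(path: str | Path) -> NetworkMetrics:
    record = json.loads(Path(path).read_text())
    fields = set(NetworkMetrics.SCALAR_FIELDS) | {"module_sizes"}
    return NetworkMetrics(**{k: v for k, v in record.items() if k in fields})
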