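"""Readers and writers for volumes, graphs, partitions, configs and reports.

Volumes travel as multi-page TIFF or HDF5 datasets in (z, y, x) order:
integer dtypes become :class:`LabelVolume`, float dtypes become
:class:`ProbabilityVolume` (validated to [0, 1]).  Graphs are JSON
(nodes with structure/slice/area/bbox, edges with weight/prob/class);
partitions are flat JSON node -> component maps; configuration is YAML.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import tifffile
import yaml

from .core import (
    ConfidenceFactors,
    EdgeClass,
    JointGraph,
    LabelVolume,
    Partition,
    ProbabilityVolume,
    Region,
    SignedGraph,
)
from .graphs import GraphBuildConfig
from .metrics import MetricsReport
from .synthetic import SyntheticSpec

__all__ = [
    "DataError",
    "read_volume",
    "write_volume",
    "write_joint_graph",
    "read_joint_graph",
    "write_edge_list_csv",
    "write_partition",
    "read_partition",
    "read_pairs_csv",
    "write_pairs_csv",
    "write_report",
    "load_config",
    "dump_config",
]

DEFAULT_H5_DATASET = "data"


class DataError(ValueError):
    """A file exists but its content violates the expected contract."""


def read_volume(
    path: Union[str, Path],
    dataset: str = DEFAULT_H5_DATASET,
    channel: str = "membrane",
) -> Union[LabelVolume, ProbabilityVolume]:
    """Read a TIFF stack or HDF5 dataset as a label or probability volume.

    Integer data become a :class:`LabelVolume`, float data a
    :class:`ProbabilityVolume` (values must lie in [0, 1]).  2D images are
    promoted to a single-slice (1, y, x) volume.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    elif path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise DataError(f"{path}: no dataset {dataset!r} (has {list(f.keys())})")
            arr = f[dataset][()]
    else:
        raise DataError(f"{path}: unknown volume format {path.suffix!r} (use .tif/.tiff/.h5/.hdf5)")
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise DataError(f"{path}: expected 2D or 3D data, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool:
        return LabelVolume(arr.astype(np.int64))
    if np.issubdtype(arr.dtype, np.floating):
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise DataError(f"{path}: float volume has values outside [0, 1]")
        return ProbabilityVolume(arr.astype(float), channel=channel)
    raise DataError(f"{path}: unsupported dtype {arr.dtype}")


def write_volume(
    vol: Union[LabelVolume, ProbabilityVolume],
    path: Union[str, Path],
    dataset: str = DEFAULT_H5_DATASET,
) -> None:
    """Write a volume as multi-page TIFF or HDF5, by file extension."""
    path = Path(path)
    data = vol.data
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int32 if data.size == 0 or data.max() < 2**31 else np.int64)
    else:
        data = data.astype(np.float32)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data, photometric="minisblack")
    elif path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset(dataset, data=data)
    else:
        raise DataError(f"{path}: unknown volume format {path.suffix!r}")


def write_joint_graph(
    jg: JointGraph,
    path: Union[str, Path],
    regions: Optional[Sequence[Region]] = None,
) -> None:
    """Serialise a joint graph (and optionally its regions) to JSON."""
    region_by_id = {r.id: r for r in regions} if regions else {}
    nodes = []
    for u in sorted(jg.graph.nodes):
        entry: Dict = {"id": u, "group": jg.node_group.get(u, "neuron")}
        r = region_by_id.get(u)
        if r is not None:
            entry.update(
                structure=r.structure.value,
                slice=r.slice_index,
                area=r.area,
                bbox=list(r.bbox),
            )
        nodes.append(entry)
    edges = [
        {
            "u": u,
            "v": v,
            "weight": w,
            "prob": p,
            "class": jg.edge_class[(u, v)].value,
        }
        for (u, v), (w, p) in sorted(jg.graph.edges.items())
    ]
    payload = {
        "confidences": dict(
            zip(("lambda_n", "lambda_m", "lambda_s", "lambda_a"), jg.confidences.as_tuple())
        ),
        "nodes": nodes,
        "edges": edges,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_joint_graph(path: Union[str, Path]) -> JointGraph:
    """Read a joint graph from the JSON layout written by :func:`write_joint_graph`."""
    payload = json.loads(Path(path).read_text())
    g = SignedGraph()
    edge_class = {}
    node_group = {}
    for n in payload["nodes"]:
        g.add_node(int(n["id"]))
        node_group[int(n["id"])] = n.get("group", "neuron")
    for e in payload["edges"]:
        u, v = int(e["u"]), int(e["v"])
        g.add_edge(u, v, float(e["weight"]), e.get("prob"))
        edge_class[(min(u, v), max(u, v))] = EdgeClass(e["class"])
    cf = ConfidenceFactors(**payload.get("confidences", {}))
    return JointGraph(graph=g, edge_class=edge_class, confidences=cf, node_group=node_group)


def write_edge_list_csv(jg: JointGraph, path: Union[str, Path]) -> None:
    """Write the edge list as ``u,v,weight,class`` CSV."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["u", "v", "weight", "class"])
        for (u, v), (weight, _p) in sorted(jg.graph.edges.items()):
            w.writerow([u, v, repr(weight), jg.edge_class[(u, v)].value])


def write_partition(part: Partition, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps({str(u): int(c) for u, c in sorted(part.labels.items())}, indent=0)
    )


def read_partition(path: Union[str, Path]) -> Partition:
    raw = json.loads(Path(path).read_text())
    return Partition(labels={int(u): int(c) for u, c in raw.items()})


def read_pairs_csv(path: Union[str, Path]) -> List[Tuple[int, int]]:
    """Read ``pre_id,post_id`` pairs (header optional)."""
    pairs: List[Tuple[int, int]] = []
    with open(path, newline="") as f:
        for row in csv.reader(f):
            if not row or not row[0].strip().lstrip("-").isdigit():
                continue
            pairs.append((int(row[0]), int(row[1])))
    return pairs


def write_pairs_csv(pairs: Sequence[Tuple[int, int]], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["pre_id", "post_id"])
        w.writerows(pairs)


def write_report(reports: Dict[str, MetricsReport], path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps({k: r.as_dict() for k, r in reports.items()}, indent=2)
    )


def load_config(path: Union[str, Path]) -> Dict:
    """Load a YAML pipeline config into typed sections.

    Recognised sections: ``synthetic`` (:class:`SyntheticSpec` fields),
    ``graph`` (:class:`GraphBuildConfig` fields), ``confidences``
    (:class:`ConfidenceFactors` fields), ``solver`` (gaec|exact), ``maps``
    (``blur_sigma``, ``noise_sd``).  Unknown keys raise.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return parse_config(raw)


def parse_config(raw: Dict) -> Dict:
    known = {"synthetic", "graph", "confidences", "solver", "maps", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise DataError(f"unknown config sections: {sorted(unknown)}")
    cfg: Dict = {}
    syn = dict(raw.get("synthetic", {}))
    if "shape" in syn:
        syn["shape"] = tuple(syn["shape"])
    if "seed" in raw:
        syn.setdefault("seed", int(raw["seed"]))
    cfg["synthetic"] = SyntheticSpec(**syn)
    cfg["graph"] = GraphBuildConfig(**raw.get("graph", {}))
    cfg["confidences"] = ConfidenceFactors(**raw.get("confidences", {}))
    cfg["solver"] = raw.get("solver", "gaec")
    maps = raw.get("maps", {})
    cfg["maps"] = {
        "blur_sigma": float(maps.get("blur_sigma", 0.0)),
        "noise_sd": float(maps.get("noise_sd", 0.0)),
    }
    return cfg


def dump_config(cfg: Dict, path: Union[str, Path]) -> None:
    """Serialise a parsed config back to YAML (round-trips through load)."""
    from dataclasses import asdict

    raw = {
        "synthetic": {**asdict(cfg["synthetic"]), "shape": list(cfg["synthetic"].shape)},
        "graph": asdict(cfg["graph"]),
        "confidences": asdict(cfg["confidences"]),
        "solver": cfg["solver"],
        "maps": dict(cfg["maps"]),
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))
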