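"""Shared domain types and the joint partitioning objective.

The package decomposes a volume of neural tissue into 3D instances by
partitioning a signed weighted graph.  Nodes are 2D regions (neuron
superpixels, mitochondria, pre-/post-synapses); edges carry real weights
whose sign encodes attraction (positive, the endpoints likely belong to the
same object) or repulsion (negative).  A feasible solution is a partition
of the node set; the cost of a partition is the total weight of the edges
it cuts, with per-structure confidence factors scaling each edge class.

Sign convention
---------------
Edge probabilities are stored as *merge* probabilities: ``p_merge`` is the
probability that the two endpoints belong to the same object.  The weight
transform is

    w = log(p_merge / (1 - p_merge)) + log((1 - beta) / beta)

so that ``p_merge > 0.5`` (at ``beta = 0.5``) gives an attractive edge.
The bias ``beta`` shifts all weights of a class: ``beta > 0.5`` pushes
toward splitting (more over-segmentation), ``beta < 0.5`` toward merging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple

import numpy as np

__all__ = [
    "Structure",
    "EdgeClass",
    "LabelVolume",
    "ProbabilityVolume",
    "Region",
    "SignedGraph",
    "ConfidenceFactors",
    "JointGraph",
    "Partition",
    "weight_from_probability",
    "objective_value",
    "is_valid_partition_solution",
    "validate_confidences",
    "PROB_CLIP",
]

#: probabilities are clipped to [PROB_CLIP, 1 - PROB_CLIP] before the logit,
#: because segmentation maps routinely contain exact 0/1 responses.
PROB_CLIP = 1e-6

Edge = Tuple[int, int]


class Structure(str, Enum):
    """Fine-grained region class."""

    NEURON = "neuron"
    MITOCHONDRION = "mitochondrion"
    PRE_SYNAPSE = "pre_synapse"
    POST_SYNAPSE = "post_synapse"


class EdgeClass(str, Enum):
    """Edge class in the joint graph; selects the confidence factor."""

    NEURON = "neuron"
    MITO = "mito"
    SYN = "syn"
    AFFILIATION = "affiliation"


def _group_of(structure: Structure) -> str:
    """Coarse node group: neuron / mito / syn."""
    if structure is Structure.NEURON:
        return "neuron"
    if structure is Structure.MITOCHONDRION:
        return "mito"
    return "syn"


class ParameterError(ValueError):
    """A hyper-parameter is outside its admissible range."""


@dataclass
class LabelVolume:
    """3D grid of non-negative integer instance labels, axis order (z, y, x).

    Label 0 is background.  ``z`` is the cutting (sectioning) axis; slices
    are the individual 2D images of the anisotropic stack.  ``voxel_size``
    is the physical voxel extent in nm per axis and is informational only.
    """

    data: np.ndarray
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D (z,y,x), got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"label volume must have integer dtype, got {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class ProbabilityVolume:
    """3D grid of probabilities in [0, 1], axis order (z, y, x).

    ``channel`` names the semantic meaning of the map (``membrane``,
    ``mitochondria``, ``pre_synapse``, ``post_synapse``).
    """

    data: np.ndarray
    channel: str = "membrane"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"probability volume must be 3D (z,y,x), got shape {self.data.shape}")
        if self.data.size and (self.data.min() < 0.0 or self.data.max() > 1.0):
            raise ValueError("probability values must lie in [0, 1]")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class Region:
    """One 2D instance on a single slice.

    ``mask`` is an (N, 2) integer array of (y, x) pixel coordinates; ``bbox``
    is the tight half-open bounding rectangle (y0, x0, y1, x1); ``area`` is
    the pixel count.  ``source_label`` records the label this region carried
    in the originating volume (used to map volume labels to node ids).
    """

    id: int
    structure: Structure
    slice_index: int
    mask: np.ndarray
    bbox: Tuple[int, int, int, int] = field(default=None)  # type: ignore[assignment]
    area: int = field(default=None)  # type: ignore[assignment]
    source_label: int = -1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.int64)
        if self.mask.ndim != 2 or self.mask.shape[1] != 2 or self.mask.shape[0] == 0:
            raise ValueError("region mask must be a non-empty (N, 2) array of (y, x) pixels")
        if self.bbox is None:
            y, x = self.mask[:, 0], self.mask[:, 1]
            self.bbox = (int(y.min()), int(x.min()), int(y.max()) + 1, int(x.max()) + 1)
        if self.area is None:
            self.area = int(self.mask.shape[0])
        if self.area != self.mask.shape[0]:
            raise ValueError("area must equal the mask pixel count")

    def mask_keys(self) -> np.ndarray:
        """Pixels encoded as single int64 keys, for fast set operations."""
        return self.mask[:, 0] << np.int64(32) | self.mask[:, 1]


@dataclass
class SignedGraph:
    """Undirected graph with real edge weights and optional merge probabilities.

    ``edges`` maps the sorted node pair ``(u, v)`` with ``u < v`` to
    ``(weight, merge_probability)``; ``merge_probability`` may be ``None``
    for edges supplied directly as weights.
    """

    nodes: Set[int] = field(default_factory=set)
    edges: Dict[Edge, Tuple[float, Optional[float]]] = field(default_factory=dict)

    def add_node(self, u: int) -> None:
        self.nodes.add(int(u))

    def add_edge(self, u: int, v: int, weight: float, merge_probability: Optional[float] = None) -> None:
        u, v = int(u), int(v)
        if u == v:
            raise ValueError(f"self-loop on node {u}")
        if u > v:
            u, v = v, u
        self.nodes.add(u)
        self.nodes.add(v)
        self.edges[(u, v)] = (float(weight), merge_probability)

    def weight(self, u: int, v: int) -> float:
        if u > v:
            u, v = v, u
        return self.edges[(u, v)][0]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class ConfidenceFactors:
    """Per-structure confidence weights of the joint objective.

    The four factors weight the neuron, mitochondria, synapse and
    affiliation edge sets; they lie in [0, 1] and sum to 1.  Setting a
    factor to 0 removes that evidence channel (e.g. ``(1, 0, 0, 0)`` is the
    plain neuron multicut baseline).
    """

    lambda_n: float = 0.25
    lambda_m: float = 0.25
    lambda_s: float = 0.25
    lambda_a: float = 0.25

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.lambda_n, self.lambda_m, self.lambda_s, self.lambda_a)

    def factor(self, edge_class: EdgeClass) -> float:
        return {
            EdgeClass.NEURON: self.lambda_n,
            EdgeClass.MITO: self.lambda_m,
            EdgeClass.SYN: self.lambda_s,
            EdgeClass.AFFILIATION: self.lambda_a,
        }[edge_class]

    def validate(self) -> None:
        if not validate_confidences(self):
            raise ParameterError(
                f"confidence factors {self.as_tuple()} must lie in [0,1] and sum to 1"
            )


def validate_confidences(cf: ConfidenceFactors, tol: float = 1e-9) -> bool:
    """True iff all four factors lie in [0, 1] and sum to 1 within ``tol``."""
    vals = cf.as_tuple()
    if any((not np.isfinite(v)) or v < 0.0 or v > 1.0 for v in vals):
        return False
    return abs(sum(vals) - 1.0) <= tol


@dataclass
class JointGraph:
    """Union graph over neuron, mitochondria and synapse nodes.

    Every edge carries exactly one :class:`EdgeClass`; affiliation edges
    join a neuron node to an ultrastructure node.  The effective weight of
    an edge is ``lambda_class * weight``; the solver and the objective
    operate on effective weights, which makes them class-agnostic.
    """

    graph: SignedGraph
    edge_class: Dict[Edge, EdgeClass]
    confidences: ConfidenceFactors = field(default_factory=ConfidenceFactors)
    node_group: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.graph.edges) - set(self.edge_class)
        if missing:
            raise ValueError(f"{len(missing)} edges lack an edge class")

    def effective_weight(self, u: int, v: int) -> float:
        if u > v:
            u, v = v, u
        return self.confidences.factor(self.edge_class[(u, v)]) * self.graph.edges[(u, v)][0]

    def effective_edges(self) -> Iterable[Tuple[int, int, float]]:
        """Yield (u, v, lambda_class * weight) over all edges."""
        for (u, v), (w, _p) in self.graph.edges.items():
            yield u, v, self.confidences.factor(self.edge_class[(u, v)]) * w

    def nodes_of_group(self, group: str) -> Set[int]:
        return {u for u, g in self.node_group.items() if g == group}

    def subgraph_of_class(self, edge_class: EdgeClass) -> SignedGraph:
        """The signed graph restricted to edges of one class (raw weights)."""
        sub = SignedGraph()
        for (u, v), (w, p) in self.graph.edges.items():
            if self.edge_class[(u, v)] is edge_class:
                sub.add_edge(u, v, w, p)
        return sub


@dataclass
class Partition:
    """A decomposition of the node set into components.

    ``labels`` maps node id to component id; component ids are contiguous
    from 0.  The induced edge indicator is ``x_e = 1`` iff the endpoints of
    ``e`` carry different component ids (1 = cut, 0 = join).
    """

    labels: Dict[int, int]
    num_components: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.num_components is None:
            self.num_components = len(set(self.labels.values()))

    def indicator(self, u: int, v: int) -> int:
        return int(self.labels[u] != self.labels[v])

    def edge_indicators(self, graph: SignedGraph) -> Dict[Edge, int]:
        return {e: int(self.labels[e[0]] != self.labels[e[1]]) for e in graph.edges}

    @classmethod
    def from_components(cls, components: Iterable[Iterable[int]]) -> "Partition":
        labels: Dict[int, int] = {}
        for comp_id, comp in enumerate(components):
            for u in comp:
                labels[u] = comp_id
        return cls(labels=labels)


def weight_from_probability(p_merge, beta: float = 0.5, clip: float = PROB_CLIP):
    """Transform a merge probability into a signed edge weight.

    ``w = logit(p_merge) + log((1 - beta) / beta)``: strictly increasing in
    ``p_merge``, strictly decreasing in ``beta``; positive weights attract,
    negative repel.  ``p_merge`` is clipped to ``[clip, 1 - clip]`` so exact
    0/1 probabilities map to large finite weights.  Accepts scalars or
    arrays.

    Parameters
    ----------
    p_merge : float or ndarray in [0, 1]
        Probability that the two endpoints belong to the same object.
    beta : float in (0, 1)
        Bias: > 0.5 lowers all weights (favours splitting), < 0.5 raises
        them (favours merging).
    """
    if not (0.0 < beta < 1.0):
        raise ParameterError(f"beta must lie strictly in (0, 1), got {beta}")
    arr = np.asarray(p_merge, dtype=float)
    if arr.size and (np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0):
        raise ParameterError("p_merge must lie in [0, 1]")
    p = np.clip(arr, clip, 1.0 - clip)
    w = np.log(p / (1.0 - p)) + math.log((1.0 - beta) / beta)
    if np.isscalar(p_merge) or arr.ndim == 0:
        return float(w)
    return w


def objective_value(jg: JointGraph, part: Partition) -> float:
    """Cost of a partition: sum of effective weights of the cut edges.

    Implements the class-weighted cut objective
    ``sum_c lambda_c * sum_{e in E_c} w_e x_e`` with ``x_e`` induced by the
    partition.  The all-join partition has cost exactly 0.
    """
    missing = jg.graph.nodes - set(part.labels)
    if missing:
        raise KeyError(f"partition misses {len(missing)} nodes, e.g. {sorted(missing)[:3]}")
    total = 0.0
    labels = part.labels
    for u, v, w_eff in jg.effective_edges():
        if labels[u] != labels[v]:
            total += w_eff
    return total


def is_valid_partition_solution(jg: JointGraph, edge_indicators: Mapping[Edge, int]) -> bool:
    """Check the cycle (no dangling edge) consistency of edge indicators.

    Indicators are feasible iff they are induced by some node partition:
    taking connected components of the join (``x_e = 0``) edges, every cut
    edge must span two different components.  Equivalently, no cycle of the
    graph contains exactly one cut edge.
    """
    for e in jg.graph.edges:
        if e not in edge_indicators:
            raise KeyError(f"edge {e} has no indicator")
    parent: Dict[int, int] = {u: u for u in jg.graph.nodes}

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    for (u, v) in jg.graph.edges:
        if not edge_indicators[(u, v)]:
            parent[find(u)] = find(v)
    return all(find(u) != find(v) for (u, v), x in edge_indicators.items() if x)
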