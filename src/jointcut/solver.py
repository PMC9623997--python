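"""Solvers for the joint partitioning objective.

Minimising the class-weighted cut subject to cycle consistency is NP-hard,
so the workhorse is the greedy additive edge contraction (GAEC) heuristic:
starting from singletons, repeatedly contract the edge with the largest
positive effective weight, replacing parallel edges by their sum, until no
positive edge remains.  Every contraction lowers the objective by the
contracted weight, so the objective trace is monotone non-increasing and
the result is feasible by construction.

For graphs of up to 12 nodes an exact brute-force oracle enumerates every
set partition; it exists to certify the heuristic on small instances.  The
26-connectivity component labeling used as the ultrastructure baseline
also lives here.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

from .core import JointGraph, LabelVolume, Partition

__all__ = [
    "gaec_solve",
    "GaecResult",
    "brute_force_solve",
    "cc_labeling_3d",
    "enumerate_partitions",
]

BRUTE_FORCE_NODE_CAP = 12


@dataclass
class GaecResult:
    """Partition plus the per-step contraction trace.

    ``merge_history`` lists ``(u_root, v_root, contracted_weight)`` in
    order; ``objective_trace`` starts at the all-singleton objective and
    records the objective after each contraction.
    """

    partition: Partition
    merge_history: List[Tuple[int, int, float]] = field(default_factory=list)
    objective_trace: List[float] = field(default_factory=list)


def _partition_from_parent(nodes, find) -> Partition:
    comps: Dict[int, List[int]] = {}
    for u in sorted(nodes):
        comps.setdefault(find(u), []).append(u)
    labels: Dict[int, int] = {}
    for comp_id, root in enumerate(sorted(comps)):
        for u in comps[root]:
            labels[u] = comp_id
    return Partition(labels=labels, num_components=len(comps))


def gaec_solve(
    jg: JointGraph,
    contract_zero: bool = False,
    return_history: bool = False,
):
    """Greedy additive edge contraction on the effective-weight graph.

    Contracts the maximum-effective-weight edge while that maximum is
    positive (zero-weight edges are on the boundary and are only contracted
    with ``contract_zero=True``); parallel edges arising from a contraction
    are merged by summation (sum linkage).  Deterministic: ties are broken
    toward the lexicographically smallest (min endpoint id, max endpoint
    id) pair, and supernodes are represented by their smallest member id.

    Returns a :class:`~jointcut.core.Partition`, or a :class:`GaecResult`
    with the merge trace when ``return_history`` is set.
    """
    nodes = jg.graph.nodes
    adj: Dict[int, Dict[int, float]] = {u: {} for u in nodes}
    for u, v, w_eff in jg.effective_edges():
        adj[u][v] = adj[v][u] = adj[u].get(v, 0.0) + w_eff

    parent: Dict[int, int] = {u: u for u in nodes}

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    threshold = -1e-300 if contract_zero else 0.0
    heap: List[Tuple[float, int, int]] = []
    for u, nbrs in adj.items():
        for v, w in nbrs.items():
            if u < v and w > threshold:
                heap.append((-w, u, v))
    heapq.heapify(heap)

    start_obj = sum(w for _u, _v, w in jg.effective_edges())
    history: List[Tuple[int, int, float]] = []
    trace: List[float] = [start_obj]

    while heap:
        neg_w, u, v = heapq.heappop(heap)
        w = -neg_w
        if w <= threshold:
            break
        # lazy deletion: entry is live iff both endpoints are still roots
        # and the recorded weight matches the current edge weight
        if parent[u] != u or parent[v] != v:
            continue
        cur = adj[u].get(v)
        if cur is None or cur != w:
            continue
        # contract v into u (u < v by construction, keep min id as root)
        parent[v] = u
        del adj[u][v]
        del adj[v][u]
        for nbr, wn in adj[v].items():
            new_w = adj[u].get(nbr, 0.0) + wn
            adj[u][nbr] = adj[nbr][u] = new_w
            del adj[nbr][v]
            if new_w > threshold:
                a, b = (u, nbr) if u < nbr else (nbr, u)
                heapq.heappush(heap, (-new_w, a, b))
        adj[v].clear()
        history.append((u, v, w))
        trace.append(trace[-1] - w)

    part = _partition_from_parent(nodes, find)
    if return_history:
        return GaecResult(partition=part, merge_history=history, objective_trace=trace)
    return part


def enumerate_partitions(n: int):
    """Yield every set partition of ``range(n)`` as a canonical label tuple.

    Canonical form is the restricted growth string: ``labels[0] = 0`` and
    each subsequent label is at most ``max(previous) + 1``; the enumeration
    is in lexicographic order of the strings.
    """
    if n == 0:
        yield ()
        return
    labels = [0] * n

    def rec(i: int, m: int):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(m + 1):
            labels[i] = lab
            yield from rec(i + 1, max(m, lab + 1))

    yield from rec(1, 1)


def brute_force_solve(jg: JointGraph) -> Tuple[Partition, float]:
    """Exact minimiser by exhaustive enumeration of set partitions.

    Refuses graphs with more than 12 nodes (Bell numbers explode).  Ties
    are broken toward fewer components, then toward the lexicographically
    smallest canonical labeling over nodes in ascending id order.
    """
    nodes = sorted(jg.graph.nodes)
    n = len(nodes)
    if n > BRUTE_FORCE_NODE_CAP:
        raise ValueError(f"brute force is capped at {BRUTE_FORCE_NODE_CAP} nodes, got {n}")
    if n == 0:
        return Partition(labels={}, num_components=0), 0.0
    index = {u: i for i, u in enumerate(nodes)}
    all_parts = np.array(list(enumerate_partitions(n)), dtype=np.int8)
    obj = np.zeros(all_parts.shape[0])
    for u, v, w_eff in jg.effective_edges():
        obj += w_eff * (all_parts[:, index[u]] != all_parts[:, index[v]])
    best = obj.min()
    cand = np.flatnonzero(obj <= best + 1e-12)
    n_comps = all_parts[cand].max(axis=1) + 1
    order = sorted(
        range(len(cand)),
        key=lambda i: (int(n_comps[i]), tuple(int(x) for x in all_parts[cand[i]])),
    )
    chosen = all_parts[cand[order[0]]]
    labels = {u: int(chosen[index[u]]) for u in nodes}
    return Partition(labels=labels), float(obj[cand[order[0]]])


def cc_labeling_3d(mask: LabelVolume) -> LabelVolume:
    """26-connectivity 3D connected-component labeling of a foreground mask.

    The classical ultrastructure baseline: any nonzero voxel is foreground,
    and voxels touching across faces, edges or corners (including across
    adjacent slices) join the same 3D instance.
    """
    fg = mask.data > 0
    labeled, _n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    return LabelVolume(labeled.astype(np.int64), voxel_size=mask.voxel_size)
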