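"""From the joint partition back to per-structure instance labelings.

The solver labels every node of the joint graph with a component id.
Restricting those labels to one structure gives that structure's instance
labeling.  Because ultrastructure nodes can be pulled into the same
component purely through neuron-level evidence (two mitochondria inside
one neuron, say), a component may contain ultrastructure regions with no
path between them in their own structure graph; such labels are split so
that every final instance is connected by primary (structure-level) edges.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import JointGraph, LabelVolume, Partition, Region, SignedGraph

__all__ = [
    "project_partition",
    "split_merged_ultrastructures",
    "multi_contact_report",
    "labels_to_volume",
]


def project_partition(jg: JointGraph, part: Partition, group: str) -> Dict[int, int]:
    """Restrict component labels to the nodes of one structure group.

    ``group`` is one of ``"neuron"``, ``"mito"``, ``"syn"``.  Labels are
    renumbered contiguously from 1 (0 is reserved for background when the
    map is painted into a volume), in order of the smallest node id of each
    component.
    """
    nodes = sorted(jg.nodes_of_group(group))
    remap: Dict[int, int] = {}
    out: Dict[int, int] = {}
    for u in nodes:
        comp = part.labels[u]
        if comp not in remap:
            remap[comp] = len(remap) + 1
        out[u] = remap[comp]
    return out


def _components(sub: SignedGraph, nodes: List[int]) -> List[List[int]]:
    """Connected components of ``sub`` restricted to ``nodes`` (any edge sign)."""
    node_set = set(nodes)
    adj: Dict[int, List[int]] = {u: [] for u in nodes}
    for (u, v) in sub.edges:
        if u in node_set and v in node_set:
            adj[u].append(v)
            adj[v].append(u)
    seen = set()
    comps: List[List[int]] = []
    for start in sorted(nodes):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def split_merged_ultrastructures(sub: SignedGraph, labels: Dict[int, int]) -> Dict[int, int]:
    """Split label classes that are disconnected in their structure graph.

    For every label class, the connected components of ``sub`` restricted
    to that class are computed; if there is more than one, the component
    containing the smallest node id keeps the label and every other
    component receives a fresh label.  Iterates until no label class is
    disconnected.  The result is a refinement of the input labeling and
    the operation is idempotent.
    """
    out = dict(labels)
    next_label = max(out.values(), default=0) + 1
    changed = True
    while changed:
        changed = False
        by_label: Dict[int, List[int]] = {}
        for u, lab in out.items():
            by_label.setdefault(lab, []).append(u)
        for lab in sorted(by_label):
            comps = _components(sub, by_label[lab])
            if len(comps) <= 1:
                continue
            changed = True
            # component with the smallest node id keeps the label
            comps.sort(key=lambda c: c[0])
            for comp in comps[1:]:
                for u in comp:
                    out[u] = next_label
                next_label += 1
    return out


def multi_contact_report(sub: SignedGraph, labels: Dict[int, int]) -> List[Tuple[int, int]]:
    """Label classes whose nodes fall into more than one structure-graph component.

    Returned before splitting, as ``(label, n_components)`` pairs: these are
    the ultrastructure instances co-assigned through neuron-level evidence
    (e.g. multi-contact synapses), a signal that plain splitting discards.
    """
    by_label: Dict[int, List[int]] = {}
    for u, lab in labels.items():
        by_label.setdefault(lab, []).append(u)
    report = []
    for lab in sorted(by_label):
        n = len(_components(sub, by_label[lab]))
        if n > 1:
            report.append((lab, n))
    return report


def labels_to_volume(
    regions: Sequence[Region],
    labels: Dict[int, int],
    shape: Tuple[int, int, int],
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelVolume:
    """Paint labeled regions into a fresh volume.

    Each region's pixel mask is written at its slice with the region's
    instance label; regions absent from ``labels`` are skipped.  Two
    regions of the same structure may not overlap.
    """
    out = np.zeros(shape, dtype=np.int64)
    for r in regions:
        if r.id not in labels:
            continue
        z = r.slice_index
        if not (0 <= z < shape[0]):
            raise ValueError(f"region {r.id} slice {z} outside volume of {shape[0]} slices")
        ys, xs = r.mask[:, 0], r.mask[:, 1]
        if ys.max() >= shape[1] or xs.max() >= shape[2]:
            raise ValueError(f"region {r.id} mask exceeds the volume plane {shape[1:]}")
        if np.any(out[z, ys, xs] != 0):
            raise ValueError(f"region {r.id} overlaps an already painted region on slice {z}")
        out[z, ys, xs] = labels[r.id]
    return LabelVolume(out, voxel_size=voxel_size)
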