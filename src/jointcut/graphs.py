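"""Construction of the neuron RAG, ultrastructure graphs and affiliation edges.

The joint graph is assembled from four edge sets:

* **neuron** edges — the region adjacency graph of 2D superpixels: 4-adjacent
  superpixels within a slice (plane-axis edges) plus vertically overlapping
  superpixels on adjacent slices (cutting-axis edges).  The merge probability
  of an edge is ``1 - mean membrane response`` over the contact interface.
* **mito** edges — candidate 3D links between 2D mitochondria regions at most
  ``slice_gap`` slices apart, weighted by a blend of bounding-box IoU and
  pixel-mask IoU.
* **syn** edges — the same attractive construction within the pre-synapse
  class and within the post-synapse class, plus one *repulsive* edge per
  (pre, post) pair: a synapse's two sides belong to different neurons.
* **affiliation** edges — a neuron superpixel and an ultrastructure region on
  the same slice are linked when their overlap exceeds an area threshold;
  the merge probability is the mean semantic-map response over the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from .core import (
    ConfidenceFactors,
    Edge,
    EdgeClass,
    JointGraph,
    LabelVolume,
    ProbabilityVolume,
    Region,
    SignedGraph,
    Structure,
    weight_from_probability,
)

__all__ = [
    "GraphBuildConfig",
    "extract_regions",
    "generate_superpixels",
    "build_neuron_rag",
    "iou_similarity",
    "build_mitochondria_graph",
    "build_synapse_graph",
    "build_affiliation_edges",
    "assemble_joint_graph",
]


@dataclass
class GraphBuildConfig:
    """Hyper-parameters of graph construction.

    ``beta_*`` are the per-class bias parameters of the weight transform
    (0.5 is neutral).  ``iou_lambda`` balances bounding-box against mask IoU
    in the ultrastructure similarity.  ``slice_gap`` is the maximum slice
    distance for candidate ultrastructure links.  ``area_threshold`` is the
    minimum pixel overlap for an affiliation edge.
    ``prepost_repulsion_prob`` is the merge probability assigned to the
    repulsive pre/post edge of a synapse pair (must be < 0.5).
    """

    beta_neuron: float = 0.5
    beta_mito: float = 0.5
    beta_syn: float = 0.5
    beta_affiliation: float = 0.5
    iou_lambda: float = 1.0
    slice_gap: int = 2
    area_threshold: int = 50
    prepost_repulsion_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.slice_gap < 1:
            raise ValueError("slice_gap must be >= 1")
        if self.area_threshold < 0:
            raise ValueError("area_threshold must be >= 0")
        if self.iou_lambda < 0:
            raise ValueError("iou_lambda must be >= 0")
        if not (0.0 < self.prepost_repulsion_prob < 0.5):
            raise ValueError("prepost_repulsion_prob must lie in (0, 0.5)")


STRUCTURE_BETA = {
    Structure.NEURON: "beta_neuron",
    Structure.MITOCHONDRION: "beta_mito",
    Structure.PRE_SYNAPSE: "beta_syn",
    Structure.POST_SYNAPSE: "beta_syn",
}


def extract_regions(
    vol: LabelVolume,
    structure: Structure,
    id_start: int = 0,
    ids_from_labels: bool = False,
) -> List[Region]:
    """Extract one :class:`Region` per (slice, label > 0) pair.

    Regions are returned sorted by (slice, label) and numbered sequentially
    from ``id_start``; with ``ids_from_labels`` the node id is the volume
    label itself, which requires labels to be unique across slices (the
    superpixel contract).
    """
    regions: List[Region] = []
    next_id = id_start
    seen_labels: Dict[int, int] = {}
    for z in range(vol.n_slices):
        sl = vol.data[z]
        idx = ndimage.value_indices(sl.astype(np.int64), ignore_value=0)
        for label in sorted(idx):
            ys, xs = idx[label]
            if ids_from_labels:
                if label in seen_labels:
                    raise ValueError(
                        f"label {label} appears on slices {seen_labels[label]} and {z}; "
                        "ids_from_labels requires globally unique per-slice labels"
                    )
                seen_labels[int(label)] = z
                rid = int(label)
            else:
                rid = next_id
                next_id += 1
            regions.append(
                Region(
                    id=rid,
                    structure=structure,
                    slice_index=z,
                    mask=np.stack([ys, xs], axis=1),
                    source_label=int(label),
                )
            )
    return regions


def generate_superpixels(boundary: ProbabilityVolume, smoothing_sigma: float = 1.0) -> LabelVolume:
    """Per-slice seeded watershed over-segmentation of a membrane map.

    Each 2D slice is smoothed with a Gaussian; the local minima of the
    smoothed map seed a watershed flood.  Superpixel labels are unique
    across slices (each slice is segmented singularly and offset).
    """
    out = np.zeros(boundary.shape, dtype=np.int64)
    offset = 0
    for z in range(boundary.shape[0]):
        sl = boundary.data[z]
        if smoothing_sigma > 0:
            sl = gaussian(sl, sigma=smoothing_sigma, preserve_range=True)
        markers, n_seeds = ndimage.label(local_minima(sl, allow_borders=True))
        if n_seeds == 0:  # constant slice: one basin
            markers = np.ones(sl.shape, dtype=np.int64)
            n_seeds = 1
        labels = watershed(sl, markers)
        out[z] = labels + offset
        offset += int(labels.max())
    return LabelVolume(out)


def _accumulate_pairs(
    a_lab: np.ndarray,
    b_lab: np.ndarray,
    a_val: np.ndarray,
    b_val: np.ndarray,
    sums: Dict[Edge, float],
    counts: Dict[Edge, int],
) -> None:
    """Accumulate boundary means over contact pixel pairs (a, b)."""
    m = (a_lab != b_lab) & (a_lab > 0) & (b_lab > 0)
    if not m.any():
        return
    u = a_lab[m].astype(np.int64)
    v = b_lab[m].astype(np.int64)
    val = 0.5 * (a_val[m] + b_val[m])
    lo = np.minimum(u, v)
    hi = np.maximum(u, v)
    keys = lo << np.int64(32) | hi
    order = np.argsort(keys, kind="stable")
    keys, val = keys[order], val[order]
    uniq, start = np.unique(keys, return_index=True)
    seg_sums = np.add.reduceat(val, start)
    seg_counts = np.diff(np.append(start, len(keys)))
    for k, s, c in zip(uniq, seg_sums, seg_counts):
        e = (int(k >> np.int64(32)), int(k & np.int64(0xFFFFFFFF)))
        sums[e] = sums.get(e, 0.0) + float(s)
        counts[e] = counts.get(e, 0) + int(c)


def build_neuron_rag(
    superpixels: LabelVolume,
    boundary: ProbabilityVolume,
    cfg: GraphBuildConfig,
) -> SignedGraph:
    """Region adjacency graph of neuron superpixels.

    Edges join 4-adjacent superpixels within a slice and vertically
    overlapping superpixels on adjacent slices.  For every contact pixel
    pair the membrane response is averaged over both pixels;
    ``p_merge = 1 - mean`` over all pairs of the interface, and the weight
    follows the logit transform with ``beta_neuron``.
    """
    if superpixels.shape != boundary.shape:
        raise ValueError(
            f"superpixels {superpixels.shape} and boundary {boundary.shape} shapes differ"
        )
    sums: Dict[Edge, float] = {}
    counts: Dict[Edge, int] = {}
    lab, bd = superpixels.data, boundary.data
    for z in range(superpixels.n_slices):
        sl, bv = lab[z], bd[z]
        _accumulate_pairs(sl[:, :-1], sl[:, 1:], bv[:, :-1], bv[:, 1:], sums, counts)
        _accumulate_pairs(sl[:-1, :], sl[1:, :], bv[:-1, :], bv[1:, :], sums, counts)
    for z in range(superpixels.n_slices - 1):
        _accumulate_pairs(lab[z], lab[z + 1], bd[z], bd[z + 1], sums, counts)

    g = SignedGraph()
    for label in np.unique(lab):
        if label > 0:
            g.add_node(int(label))
    for (u, v), s in sums.items():
        p_merge = 1.0 - s / counts[(u, v)]
        g.add_edge(u, v, weight_from_probability(p_merge, cfg.beta_neuron), p_merge)
    return g


def iou_similarity(u: Region, v: Region, iou_lambda: float = 1.0) -> float:
    """Blend of bounding-box IoU and in-plane mask IoU, in [0, 1].

    ``(D_uv + lambda * S_uv) / (1 + lambda)`` where ``D_uv`` is the IoU of
    the tight bounding boxes and ``S_uv`` the IoU of the pixel masks, both
    compared in the (y, x) plane ignoring the slice offset (the stack is
    assumed aligned).
    """
    uy0, ux0, uy1, ux1 = u.bbox
    vy0, vx0, vy1, vx1 = v.bbox
    iy = max(0, min(uy1, vy1) - max(uy0, vy0))
    ix = max(0, min(ux1, vx1) - max(ux0, vx0))
    inter_box = iy * ix
    union_box = (uy1 - uy0) * (ux1 - ux0) + (vy1 - vy0) * (vx1 - vx0) - inter_box
    d_uv = inter_box / union_box if union_box else 0.0
    if inter_box == 0:
        s_uv = 0.0
    else:
        inter_mask = np.intersect1d(u.mask_keys(), v.mask_keys()).size
        s_uv = inter_mask / (u.area + v.area - inter_mask)
    return (d_uv + iou_lambda * s_uv) / (1.0 + iou_lambda)


def _attractive_overlap_edges(
    regions: Sequence[Region],
    cfg: GraphBuildConfig,
    beta: float,
    g: SignedGraph,
) -> None:
    """Add IoU-weighted edges between regions at most ``slice_gap`` apart."""
    by_slice: Dict[int, List[Region]] = {}
    for r in regions:
        g.add_node(r.id)
        by_slice.setdefault(r.slice_index, []).append(r)
    for z in sorted(by_slice):
        for dz in range(1, cfg.slice_gap + 1):
            for u in by_slice[z]:
                for v in by_slice.get(z + dz, []):
                    p = iou_similarity(u, v, cfg.iou_lambda)
                    if p > 0.0:
                        g.add_edge(u.id, v.id, weight_from_probability(p, beta), p)


def build_mitochondria_graph(regions: Sequence[Region], cfg: GraphBuildConfig) -> SignedGraph:
    """Candidate-link graph between 2D mitochondria regions.

    Edge (u, v) exists iff the regions lie at most ``slice_gap`` slices
    apart and their IoU similarity is positive; the similarity is the merge
    probability.  All edges are attractive or neutral by construction.
    """
    for r in regions:
        if r.structure is not Structure.MITOCHONDRION:
            raise ValueError(f"region {r.id} is {r.structure.value}, expected mitochondrion")
    g = SignedGraph()
    _attractive_overlap_edges(regions, cfg, cfg.beta_mito, g)
    return g


def build_synapse_graph(
    pre_regions: Sequence[Region],
    post_regions: Sequence[Region],
    pairs: Sequence[Tuple[int, int]],
    cfg: GraphBuildConfig,
) -> SignedGraph:
    """Synapse graph: attractive within pre and within post, repulsive across.

    The attractive edges are built exactly as for mitochondria, separately
    within the pre-synapse class and within the post-synapse class.  Each
    listed (pre id, post id) pair adds one repulsive edge with merge
    probability ``prepost_repulsion_prob`` — the not-link information that a
    synapse's two sides belong to different neurons.
    """
    g = SignedGraph()
    _attractive_overlap_edges(pre_regions, cfg, cfg.beta_syn, g)
    _attractive_overlap_edges(post_regions, cfg, cfg.beta_syn, g)
    pre_ids = {r.id for r in pre_regions}
    post_ids = {r.id for r in post_regions}
    for pre_id, post_id in pairs:
        if pre_id not in pre_ids:
            raise KeyError(f"pair references unknown pre-synapse region {pre_id}")
        if post_id not in post_ids:
            raise KeyError(f"pair references unknown post-synapse region {post_id}")
        p = cfg.prepost_repulsion_prob
        g.add_edge(pre_id, post_id, weight_from_probability(p, cfg.beta_syn), p)
    return g


def derive_synapse_pairs(
    pre_regions: Sequence[Region],
    post_regions: Sequence[Region],
    union_mask: LabelVolume,
) -> List[Tuple[int, int]]:
    """Infer (pre, post) region pairs from a union synapse mask.

    ``union_mask`` is any volume whose foreground covers whole synaptic
    clefts (e.g. a thresholded union channel).  On each slice, every
    2D connected component of the foreground that contains at least one
    pre and one post region pairs each contained pre with each contained
    post.  A region counts as contained when the majority of its pixels
    lie inside the component.
    """
    pairs: List[Tuple[int, int]] = []
    by_slice: Dict[int, Tuple[List[Region], List[Region]]] = {}
    for r in pre_regions:
        by_slice.setdefault(r.slice_index, ([], []))[0].append(r)
    for r in post_regions:
        by_slice.setdefault(r.slice_index, ([], []))[1].append(r)
    for z, (pres, posts) in sorted(by_slice.items()):
        if not pres or not posts:
            continue
        comp, _n = ndimage.label(union_mask.data[z] > 0)

        def majority_component(r: Region) -> int:
            vals = comp[r.mask[:, 0], r.mask[:, 1]]
            vals = vals[vals > 0]
            if vals.size * 2 <= r.area:
                return 0
            return int(np.bincount(vals).argmax())

        pre_comp = {r.id: majority_component(r) for r in pres}
        post_comp = {r.id: majority_component(r) for r in posts}
        for pr in sorted(pre_comp):
            for po in sorted(post_comp):
                c = pre_comp[pr]
                if c > 0 and c == post_comp[po]:
                    pairs.append((pr, po))
    return pairs


def build_affiliation_edges(
    neuron_regions: Sequence[Region],
    ultra_regions: Sequence[Region],
    prob: Optional[ProbabilityVolume],
    cfg: GraphBuildConfig,
) -> List[Tuple[Edge, float, float]]:
    """Affiliation edges between neuron superpixels and ultrastructure regions.

    For a neuron region ``u`` and an ultrastructure region ``v`` on the
    same slice, an edge is created when their pixel overlap exceeds
    ``area_threshold``; the merge probability is the mean of the semantic
    probability map over the overlap pixels (1.0 when ``prob`` is ``None``,
    e.g. for manually annotated masks).

    Returns a list of ``((u, v), weight, p_merge)`` triples.
    """
    by_slice: Dict[int, List[Region]] = {}
    for r in neuron_regions:
        by_slice.setdefault(r.slice_index, []).append(r)
    out: List[Tuple[Edge, float, float]] = []
    for v in ultra_regions:
        v_keys = v.mask_keys()
        order = np.argsort(v_keys)
        v_keys_sorted = v_keys[order]
        for u in by_slice.get(v.slice_index, []):
            pos = np.searchsorted(v_keys_sorted, u.mask_keys())
            pos = np.clip(pos, 0, v_keys_sorted.size - 1)
            hit = v_keys_sorted[pos] == u.mask_keys()
            overlap = int(hit.sum())
            if overlap <= cfg.area_threshold:
                continue
            if prob is None:
                p_merge = 1.0
            else:
                pix = u.mask[hit]
                p_merge = float(prob.data[v.slice_index, pix[:, 0], pix[:, 1]].mean())
            w = weight_from_probability(p_merge, cfg.beta_affiliation)
            out.append(((u.id, v.id), w, p_merge))
    return out


def assemble_joint_graph(
    neuron_g: SignedGraph,
    mito_g: SignedGraph,
    syn_g: SignedGraph,
    affiliation: Iterable[Tuple[Edge, float, float]],
    cf: ConfidenceFactors,
    syn_groups: Optional[Dict[int, str]] = None,
) -> JointGraph:
    """Union the four edge sets into a :class:`JointGraph`.

    Node id spaces of the three structure graphs must be disjoint.
    Dropping a structure (empty graph plus a zero confidence factor,
    renormalised) reproduces the ablation variants: neuron-only is the
    plain multicut baseline, zeroing the neuron and affiliation factors is
    the ultrastructure-only baseline.
    """
    cf.validate()
    for a, b, name in (
        (neuron_g.nodes, mito_g.nodes, "neuron/mito"),
        (neuron_g.nodes, syn_g.nodes, "neuron/syn"),
        (mito_g.nodes, syn_g.nodes, "mito/syn"),
    ):
        clash = a & b
        if clash:
            raise ValueError(f"node id collision between {name} graphs: {sorted(clash)[:5]}")

    g = SignedGraph()
    edge_class: Dict[Edge, EdgeClass] = {}
    node_group: Dict[int, str] = {}
    for src, klass, group in (
        (neuron_g, EdgeClass.NEURON, "neuron"),
        (mito_g, EdgeClass.MITO, "mito"),
        (syn_g, EdgeClass.SYN, "syn"),
    ):
        for u in src.nodes:
            g.add_node(u)
            node_group[u] = group
        for (u, v), (w, p) in src.edges.items():
            g.add_edge(u, v, w, p)
            edge_class[(u, v)] = klass

    ultra_nodes = mito_g.nodes | syn_g.nodes
    for (u, v), w, p in affiliation:
        n_end = u if u in neuron_g.nodes else v
        x_end = v if n_end == u else u
        if n_end not in neuron_g.nodes or x_end not in ultra_nodes:
            raise ValueError(f"affiliation edge {(u, v)} must join a neuron and an ultrastructure node")
        g.add_edge(u, v, w, p)
        edge_class[(min(u, v), max(u, v))] = EdgeClass.AFFILIATION
    if syn_groups:
        node_group.update(syn_groups)
    return JointGraph(graph=g, edge_class=edge_class, confidences=cf, node_group=node_group)
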