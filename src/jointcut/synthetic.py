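"""Synthetic anisotropic EM-style volumes with known ground truth.

The generator emulates the geometry the joint model relies on, not EM
texture: neurons are z-extruded bands whose mutual boundaries jitter from
slice to slice (anisotropic stack, imperfect alignment); each mitochondrion
is a blob lying strictly inside one neuron across several slices; each
synapse places a pre-synaptic region in one neuron and its post-synaptic
partner directly across the membrane in the adjacent neuron.  Neuron
cross-sections are then over-segmented into random connected fragments
(the superpixel stage is assumed to avoid under-segmentation), and edge
merge probabilities are corrupted at the *edge* level: an edge is ideal
(0.9 within a neuron, 0.1 across) unless flipped across 0.5 with
probability ``edge_noise_rate``, plus uniform jitter.

Everything is a pure function of the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from skimage.filters import gaussian
from skimage.segmentation import find_boundaries, watershed

from .core import (
    PROB_CLIP,
    ConfidenceFactors,
    EdgeClass,
    JointGraph,
    LabelVolume,
    ProbabilityVolume,
    SignedGraph,
    weight_from_probability,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_ground_truth",
    "fragment_neurons",
    "refinement_mapping",
    "corrupt_edge_probabilities",
    "generate_probability_maps",
    "consensus_fixture",
]

#: ideal merge probabilities: +/- ln 9 weights at beta = 0.5
IDEAL_P_WITHIN = 0.9
IDEAL_P_BETWEEN = 0.1


@dataclass
class SyntheticSpec:
    """Study conditions of one synthetic volume.

    ``shape`` is (z, y, x); neurons are y-bands, so ``shape[1]`` must give
    every neuron at least 8 rows.  ``edge_noise_rate`` is the probability
    that a neuron edge's probability is flipped across 0.5 (must stay below
    0.5 so corruption remains information-preserving);
    ``noise_magnitude`` is the half-width of the uniform jitter added to
    each edge probability.
    """

    shape: Tuple[int, int, int] = (8, 64, 64)
    n_neurons: int = 3
    n_mito: int = 3
    n_synapse_pairs: int = 2
    fragments_per_neuron_per_slice: int = 3
    edge_noise_rate: float = 0.2
    noise_magnitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.edge_noise_rate < 0.5):
            raise ValueError("edge_noise_rate must lie in [0, 0.5)")
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")


@dataclass
class GroundTruth:
    """Ground-truth volumes plus the synapse instance pairing."""

    neurons: LabelVolume
    mito: LabelVolume
    pre: LabelVolume
    post: LabelVolume
    pairs: List[Tuple[int, int]] = field(default_factory=list)


def _band_boundaries(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-slice jittered y-boundaries between neuron bands, shape (z, n-1)."""
    z, y, _x = spec.shape
    base = np.array([(i + 1) * y // spec.n_neurons for i in range(spec.n_neurons - 1)])
    jitter = rng.integers(-1, 2, size=(z, base.size))
    return base[None, :] + jitter


def generate_ground_truth(spec: SyntheticSpec) -> GroundTruth:
    """Build ground-truth neuron, mitochondria and synapse volumes.

    Neurons tile the (y, x) plane as bands labeled 1..n; mitochondria
    (labels 1..n_mito) span most of the stack inside one neuron; each
    synapse pair k places pre instance k and post instance k on two
    consecutive slices on either side of a neuron boundary.  Raises when
    the requested structures do not fit.
    """
    z, y, x = spec.shape
    rng = np.random.default_rng([spec.seed, 0])
    band_h = y // spec.n_neurons
    if band_h < 8:
        raise ValueError(f"overcrowded: bands of {band_h} rows (< 8) for {spec.n_neurons} neurons")
    if z < 2:
        raise ValueError("need at least 2 slices")

    bounds = _band_boundaries(spec, rng)
    neurons = np.zeros(spec.shape, dtype=np.int64)
    rows = np.arange(y)
    for zi in range(z):
        neurons[zi] = 1 + np.searchsorted(bounds[zi], rows, side="right")[:, None] * np.ones(
            (1, x), dtype=np.int64
        )

    # one disjoint x-slot per ultrastructure object
    n_objects = spec.n_mito + spec.n_synapse_pairs
    slot_w = x // max(n_objects, 1)
    if n_objects and slot_w < 9:
        raise ValueError(f"overcrowded: x-slots of {slot_w} px (< 9) for {n_objects} ultrastructures")

    mito = np.zeros(spec.shape, dtype=np.int64)
    base_bounds = np.concatenate([[0], [(i + 1) * y // spec.n_neurons for i in range(spec.n_neurons - 1)], [y]])
    for j in range(spec.n_mito):
        label = j + 1
        neuron_idx = j % spec.n_neurons
        lo, hi = int(base_bounds[neuron_idx]) + 2, int(base_bounds[neuron_idx + 1]) - 2
        if hi - lo < 7:
            raise ValueError("overcrowded: neuron band too thin for a 7-row mitochondrion")
        y0 = int(rng.integers(lo, hi - 7 + 1))
        x0 = j * slot_w + 1 + int(rng.integers(0, slot_w - 8))
        z0 = int(rng.integers(0, min(2, z - 1)))
        z1 = min(z, max(z0 + 2, z - int(rng.integers(0, 2))))
        mito[z0:z1, y0 : y0 + 7, x0 : x0 + 7] = label

    pre = np.zeros(spec.shape, dtype=np.int64)
    post = np.zeros(spec.shape, dtype=np.int64)
    pairs: List[Tuple[int, int]] = []
    if spec.n_synapse_pairs and spec.n_neurons < 2:
        raise ValueError("synapse pairs need at least two neurons")
    for k in range(spec.n_synapse_pairs):
        label = k + 1
        b = int(base_bounds[1 + (k % (spec.n_neurons - 1))])
        slot = spec.n_mito + k
        x0 = slot * slot_w + 1 + int(rng.integers(0, slot_w - 6))
        z0 = int(rng.integers(0, z - 1))
        # pre strictly inside the upper band, post inside the lower one,
        # with 2-row margins so +/-1 boundary jitter never crosses them
        pre[z0 : z0 + 2, b - 5 : b - 2, x0 : x0 + 5] = label
        post[z0 : z0 + 2, b + 2 : b + 5, x0 : x0 + 5] = label
        pairs.append((label, label))

    return GroundTruth(
        neurons=LabelVolume(neurons),
        mito=LabelVolume(mito),
        pre=LabelVolume(pre),
        post=LabelVolume(post),
        pairs=pairs,
    )


def fragment_neurons(neuron_gt: LabelVolume, spec: SyntheticSpec) -> LabelVolume:
    """Over-segment every neuron cross-section into random connected fragments.

    Each (slice, neuron) cross-section is split into
    ``fragments_per_neuron_per_slice`` connected pieces by a geodesic
    watershed from random seed pixels.  Fragment labels are globally
    unique; the result is a strict refinement of ``neuron_gt`` (fragments
    never cross neuron boundaries).
    """
    k = spec.fragments_per_neuron_per_slice
    if k < 1:
        raise ValueError("fragments_per_neuron_per_slice must be >= 1")
    rng = np.random.default_rng([spec.seed, 1])
    out = np.zeros(neuron_gt.shape, dtype=np.int64)
    next_label = 1
    for z in range(neuron_gt.n_slices):
        sl = neuron_gt.data[z]
        for lab in np.unique(sl):
            if lab == 0:
                continue
            mask = sl == lab
            n_pix = int(mask.sum())
            if k > n_pix:
                raise ValueError(f"cannot cut {n_pix}-pixel cross-section into {k} fragments")
            if k == 1:
                out[z][mask] = next_label
                next_label += 1
                continue
            ys, xs = np.nonzero(mask)
            seeds = rng.choice(n_pix, size=k, replace=False)
            markers = np.zeros(sl.shape, dtype=np.int64)
            markers[ys[seeds], xs[seeds]] = np.arange(next_label, next_label + k)
            frag = watershed(np.zeros(sl.shape), markers, mask=mask)
            out[z][mask] = frag[mask]
            next_label += k
    return LabelVolume(out, voxel_size=neuron_gt.voxel_size)


def refinement_mapping(fine: LabelVolume, coarse: LabelVolume) -> Dict[int, int]:
    """Map each fine label to the coarse label it lies inside.

    Assumes (and checks) that ``fine`` is a refinement of ``coarse``.
    """
    f = fine.data.ravel()
    c = coarse.data.ravel()
    labels, first = np.unique(f, return_index=True)
    mapping: Dict[int, int] = {}
    for lab, idx in zip(labels, first):
        if lab == 0:
            continue
        mapping[int(lab)] = int(c[idx])
    # refinement check: every fine label must sit inside a single coarse label
    order = np.argsort(f, kind="stable")
    fs, cs = f[order], c[order]
    starts = np.searchsorted(fs, labels)
    for lab, s, e in zip(labels, starts, np.append(starts[1:], len(fs))):
        if lab == 0:
            continue
        if np.unique(cs[s:e]).size != 1:
            raise ValueError(f"label {lab} spans multiple coarse labels: not a refinement")
    return mapping


def corrupt_edge_probabilities(
    g: SignedGraph,
    gt: Dict[int, int],
    edge_noise_rate: float,
    noise_magnitude: float,
    seed: int,
    beta: float = 0.5,
    p_within: float = IDEAL_P_WITHIN,
    p_between: float = IDEAL_P_BETWEEN,
) -> SignedGraph:
    """Replace edge probabilities by corrupted ideal ones.

    Every node must carry a ground-truth neuron label in ``gt``.  An edge
    within a neuron gets ideal probability ``p_within`` (0.9), an edge
    across neurons ``p_between`` (0.1); with probability
    ``edge_noise_rate`` the probability is flipped across 0.5, then a
    uniform jitter of +/- ``noise_magnitude`` is added and the result is
    clipped into (0, 1).  Weights are recomputed with ``beta``.
    Deterministic given the seed.
    """
    rng = np.random.default_rng([int(seed), 2])
    out = SignedGraph(nodes=set(g.nodes))
    for (u, v) in sorted(g.edges):
        ideal = p_within if gt[u] == gt[v] else p_between
        if rng.random() < edge_noise_rate:
            ideal = 1.0 - ideal
        p = ideal + (rng.uniform(-noise_magnitude, noise_magnitude) if noise_magnitude else 0.0)
        p = float(np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP))
        out.add_edge(u, v, weight_from_probability(p, beta), p)
    return out


def generate_probability_maps(
    gt: GroundTruth,
    blur_sigma: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Dict[str, ProbabilityVolume]:
    """Blurred noisy indicator maps standing in for semantic network output.

    ``membrane`` is the per-slice thick boundary indicator of the neuron
    labels; ``mitochondria``, ``pre_synapse`` and ``post_synapse`` are the
    foreground indicators of the respective masks.  Blur is applied per
    slice (anisotropic stack), Gaussian noise is added, and values are
    clipped back to [0, 1].  With zero blur and noise the maps are exactly
    binary.
    """
    rng = np.random.default_rng([int(seed), 3])

    def _make(ind: np.ndarray, channel: str) -> ProbabilityVolume:
        m = ind.astype(float)
        if blur_sigma > 0:
            m = np.stack([gaussian(m[z], sigma=blur_sigma, preserve_range=True) for z in range(m.shape[0])])
        if noise_sd > 0:
            m = m + rng.normal(0.0, noise_sd, size=m.shape)
        return ProbabilityVolume(np.clip(m, 0.0, 1.0), channel=channel)

    membrane = np.stack(
        [find_boundaries(gt.neurons.data[z], mode="thick") for z in range(gt.neurons.n_slices)]
    )
    return {
        "membrane": _make(membrane, "membrane"),
        "mitochondria": _make(gt.mito.data > 0, "mitochondria"),
        "pre_synapse": _make(gt.pre.data > 0, "pre_synapse"),
        "post_synapse": _make(gt.post.data > 0, "post_synapse"),
    }


def consensus_fixture():
    """Deterministic two-neuron graph where only joint evidence rescues the cut.

    Two neuron chains A = {1, 2, 3} and B = {4, 5, 6} run through three
    slices.  Two of the seven neuron edges carry adversarially wrong
    probabilities: the within-A edge 1-2 looks repulsive (false split) and
    the cross edge 2-5 looks attractive (false merge).  A mitochondrion
    chain {7, 8, 9} inside A is affiliated with each A-fragment, restoring
    the 1-2 link; a synapse (pre 10 in A, post 11 in B) contributes the
    repulsive not-link that neutralises the false 2-5 attraction.

    Returns ``(joint_graph, neuron_ground_truth)`` where the ground truth
    is the set of neuron-node components ``{{1,2,3}, {4,5,6}}``.
    Partitioning the neuron subgraph alone (confidences (1,0,0,0)) fails
    on this instance; the joint graph with uniform confidences succeeds.
    """
    a1, a2, a3, b1, b2, b3 = 1, 2, 3, 4, 5, 6
    m1, m2, m3, pre, post = 7, 8, 9, 10, 11
    g = SignedGraph()
    edge_class = {}

    def add(u, v, p, klass):
        g.add_edge(u, v, weight_from_probability(p), p)
        edge_class[(min(u, v), max(u, v))] = klass

    # neuron chain edges; 1-2 and 2-5 are the corrupted ones
    add(a1, a2, 0.1, EdgeClass.NEURON)   # true 0.9: false split
    add(a2, a3, 0.9, EdgeClass.NEURON)
    add(b1, b2, 0.9, EdgeClass.NEURON)
    add(b2, b3, 0.9, EdgeClass.NEURON)
    add(a1, b1, 0.1, EdgeClass.NEURON)
    add(a2, b2, 0.9, EdgeClass.NEURON)   # true 0.1: false merge
    add(a3, b3, 0.1, EdgeClass.NEURON)
    # mitochondrion chain inside A
    add(m1, m2, 0.95, EdgeClass.MITO)
    add(m2, m3, 0.95, EdgeClass.MITO)
    # synapse not-link between A and B
    add(pre, post, 0.05, EdgeClass.SYN)
    # affiliations
    for u, v in ((m1, a1), (m2, a2), (m3, a3), (pre, a2), (post, b2)):
        add(u, v, 0.95, EdgeClass.AFFILIATION)

    node_group = {u: "neuron" for u in (a1, a2, a3, b1, b2, b3)}
    node_group.update({u: "mito" for u in (m1, m2, m3)})
    node_group.update({pre: "syn", post: "syn"})
    jg = JointGraph(
        graph=g,
        edge_class=edge_class,
        confidences=ConfidenceFactors(0.25, 0.25, 0.25, 0.25),
        node_group=node_group,
    )
    ground_truth = frozenset({frozenset({a1, a2, a3}), frozenset({b1, b2, b3})})
    return jg, ground_truth
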