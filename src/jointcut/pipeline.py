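"""End-to-end reconstruction pipeline: volumes -> graphs -> partition -> labels.

The synthetic pipeline mirrors the full method on generated data: fragment
the neurons, build the neuron RAG (topology from fragment adjacency, edge
probabilities from the seeded edge-corruption model), build the
mitochondria and synapse graphs and the affiliation edges from the
semantic maps, assemble the joint graph, solve with GAEC, project the
partition back per structure, split ultrastructure labels merged only
through neuron evidence, and score everything against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import (
    ConfidenceFactors,
    JointGraph,
    LabelVolume,
    Partition,
    ProbabilityVolume,
    Region,
    Structure,
)
from .graphs import (
    GraphBuildConfig,
    assemble_joint_graph,
    build_affiliation_edges,
    build_mitochondria_graph,
    build_neuron_rag,
    build_synapse_graph,
    extract_regions,
)
from .metrics import MetricsReport, compute_metrics_report
from .postprocess import labels_to_volume, project_partition, split_merged_ultrastructures
from .solver import brute_force_solve, gaec_solve
from .synthetic import (
    GroundTruth,
    SyntheticSpec,
    corrupt_edge_probabilities,
    fragment_neurons,
    generate_ground_truth,
    generate_probability_maps,
    refinement_mapping,
)

__all__ = ["PipelineResult", "run_synthetic_pipeline", "combined_synapse_volume", "SYNTHETIC_GRAPH_CONFIG"]

#: graph-construction defaults sized for the synthetic volumes: regions are
#: tens of pixels, so the affiliation overlap threshold is 10 px rather
#: than the 50 px appropriate for full-resolution EM regions.
SYNTHETIC_GRAPH_CONFIG = GraphBuildConfig(area_threshold=10)


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    joint_graph: JointGraph
    partition: Partition
    ground_truth: GroundTruth
    fragments: LabelVolume
    label_volumes: Dict[str, LabelVolume]
    label_maps: Dict[str, Dict[int, int]]
    reports: Dict[str, MetricsReport]
    ultra_fragment_mask: np.ndarray
    regions: Dict[str, List[Region]]


def combined_synapse_volume(pre: LabelVolume, post: LabelVolume) -> LabelVolume:
    """Merge pre and post instance volumes into one with disjoint labels."""
    offset = int(pre.data.max())
    out = pre.data.copy()
    out[post.data > 0] = post.data[post.data > 0] + offset
    return LabelVolume(out, voxel_size=pre.voxel_size)


def _region_pairs(
    pre_regions: List[Region],
    post_regions: List[Region],
    instance_pairs: List[Tuple[int, int]],
) -> List[Tuple[int, int]]:
    """One repulsive (pre, post) region pair per shared slice of each instance pair."""
    pre_by = {}
    for r in pre_regions:
        pre_by.setdefault(r.source_label, {})[r.slice_index] = r.id
    post_by = {}
    for r in post_regions:
        post_by.setdefault(r.source_label, {})[r.slice_index] = r.id
    pairs: List[Tuple[int, int]] = []
    for pre_lab, post_lab in instance_pairs:
        shared = sorted(set(pre_by.get(pre_lab, {})) & set(post_by.get(post_lab, {})))
        for z in shared:
            pairs.append((pre_by[pre_lab][z], post_by[post_lab][z]))
    return pairs


def run_synthetic_pipeline(
    spec: SyntheticSpec,
    graph_cfg: Optional[GraphBuildConfig] = None,
    confidences: Optional[ConfidenceFactors] = None,
    solver: str = "gaec",
    map_blur_sigma: float = 0.0,
    map_noise_sd: float = 0.0,
) -> PipelineResult:
    """Run the full method on one synthetic volume and score it.

    ``solver`` is ``"gaec"`` or ``"exact"`` (exact only for tiny graphs).
    With ``spec.edge_noise_rate == 0`` and zero map noise the
    reconstruction is exact for all three structures.
    """
    cfg = graph_cfg if graph_cfg is not None else SYNTHETIC_GRAPH_CONFIG
    cf = confidences if confidences is not None else ConfidenceFactors()
    cf.validate()

    gt = generate_ground_truth(spec)
    frags = fragment_neurons(gt.neurons, spec)
    frag_to_neuron = refinement_mapping(frags, gt.neurons)
    maps = generate_probability_maps(gt, map_blur_sigma, map_noise_sd, seed=spec.seed)

    neuron_regions = extract_regions(frags, Structure.NEURON, ids_from_labels=True)
    id_start = max((r.id for r in neuron_regions), default=0) + 1
    mito_regions = extract_regions(gt.mito, Structure.MITOCHONDRION, id_start=id_start)
    id_start += len(mito_regions)
    pre_regions = extract_regions(gt.pre, Structure.PRE_SYNAPSE, id_start=id_start)
    id_start += len(pre_regions)
    post_regions = extract_regions(gt.post, Structure.POST_SYNAPSE, id_start=id_start)

    # neuron RAG: topology from fragment adjacency, probabilities from the
    # seeded edge-corruption model (the membrane map fixes the topology only)
    zero_boundary = ProbabilityVolume(np.zeros(frags.shape), channel="membrane")
    rag_topology = build_neuron_rag(frags, zero_boundary, cfg)
    neuron_g = corrupt_edge_probabilities(
        rag_topology,
        frag_to_neuron,
        spec.edge_noise_rate,
        spec.noise_magnitude,
        seed=spec.seed,
        beta=cfg.beta_neuron,
    )

    mito_g = build_mitochondria_graph(mito_regions, cfg)
    syn_g = build_synapse_graph(
        pre_regions, post_regions, _region_pairs(pre_regions, post_regions, gt.pairs), cfg
    )
    affiliation = (
        build_affiliation_edges(neuron_regions, mito_regions, maps["mitochondria"], cfg)
        + build_affiliation_edges(neuron_regions, pre_regions, maps["pre_synapse"], cfg)
        + build_affiliation_edges(neuron_regions, post_regions, maps["post_synapse"], cfg)
    )
    syn_groups = {r.id: "syn" for r in pre_regions + post_regions}
    jg = assemble_joint_graph(neuron_g, mito_g, syn_g, affiliation, cf, syn_groups=syn_groups)

    if solver == "gaec":
        part = gaec_solve(jg)
    elif solver == "exact":
        part, _ = brute_force_solve(jg)
    else:
        raise ValueError(f"unknown solver {solver!r}")

    # project back per structure; split ultrastructure labels that are only
    # connected through neuron-level evidence
    neuron_labels = project_partition(jg, part, "neuron")
    mito_labels = split_merged_ultrastructures(mito_g, project_partition(jg, part, "mito"))
    syn_labels = split_merged_ultrastructures(syn_g, project_partition(jg, part, "syn"))

    shape = spec.shape
    vol_neuron = labels_to_volume(neuron_regions, neuron_labels, shape)
    vol_mito = labels_to_volume(mito_regions, mito_labels, shape)
    vol_syn = labels_to_volume(pre_regions + post_regions, syn_labels, shape)

    syn_gt = combined_synapse_volume(gt.pre, gt.post)
    reports = {
        "neuron": compute_metrics_report(vol_neuron, gt.neurons),
        "mito": compute_metrics_report(vol_mito, gt.mito),
        "synapse": compute_metrics_report(vol_syn, syn_gt),
    }

    affiliated = {e[0] for e, _w, _p in affiliation} | {e[1] for e, _w, _p in affiliation}
    ultra_frag_labels = [r.source_label for r in neuron_regions if r.id in affiliated]
    ultra_mask = np.isin(frags.data, ultra_frag_labels)

    return PipelineResult(
        joint_graph=jg,
        partition=part,
        ground_truth=gt,
        fragments=frags,
        label_volumes={"neuron": vol_neuron, "mito": vol_mito, "synapse": vol_syn},
        label_maps={"neuron": neuron_labels, "mito": mito_labels, "synapse": syn_labels},
        reports=reports,
        ultra_fragment_mask=ultra_mask,
        regions={
            "neuron": neuron_regions,
            "mito": mito_regions,
            "pre": pre_regions,
            "post": post_regions,
        },
    )
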