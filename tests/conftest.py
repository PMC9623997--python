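import numpy as np
import pytest

from jointcut.core import ConfidenceFactors, EdgeClass, JointGraph, SignedGraph


def make_single_class_graph(edges, nodes=(), edge_class=EdgeClass.NEURON):
    """Joint graph with one edge class at full confidence.

    ``edges`` is an iterable of (u, v, weight); extra isolated ``nodes``
    may be supplied.  Effective weights equal raw weights.
    """
    g = SignedGraph()
    for u in nodes:
        g.add_node(u)
    for u, v, w in edges:
        g.add_edge(u, v, w)
    lam = {
        EdgeClass.NEURON: ConfidenceFactors(1, 0, 0, 0),
        EdgeClass.MITO: ConfidenceFactors(0, 1, 0, 0),
        EdgeClass.SYN: ConfidenceFactors(0, 0, 1, 0),
        EdgeClass.AFFILIATION: ConfidenceFactors(0, 0, 0, 1),
    }[edge_class]
    return JointGraph(
        graph=g,
        edge_class={e: edge_class for e in g.edges},
        confidences=lam,
        node_group={u: "neuron" for u in g.nodes},
    )


def random_signed_graph(rng, n_nodes, edge_prob=0.5, scale=2.0):
    """Erdos-Renyi graph with mixed-sign Gaussian weights."""
    edges = []
    for u in range(n_nodes):
        for v in range(u + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((u, v, float(rng.normal(0.0, scale))))
    return make_single_class_graph(edges, nodes=range(n_nodes))


@pytest.fixture
def triangle():
    """The hand-traced triangle: ab +2, ac -5, bc +1; optimum {a,b}|{c} at -4."""
    return make_single_class_graph([(0, 1, 2.0), (0, 2, -5.0), (1, 2, 1.0)])
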