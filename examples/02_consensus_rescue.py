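"""Connectivity consensus repairing corrupted neuron edge weights.

Two neuron chains run through three slices; two of the seven boundary-cue
edges carry adversarially wrong probabilities (one false split inside
chain A, one false merge between the chains).  A mitochondrion chain
inside A supplies link information, and a synapse between A and B
supplies not-link information.  Partitioning the neuron graph alone
reproduces both errors; the joint graph recovers the truth.
"""

from jointcut import ConfidenceFactors, gaec_solve
from jointcut.synthetic import consensus_fixture


def neuron_partition(part):
    comps = {}
    for u in range(1, 7):
        comps.setdefault(part.labels[u], []).append(u)
    return sorted(sorted(c) for c in comps.values())


jg, ground_truth = consensus_fixture()

joint = gaec_solve(jg)
print("joint solve      :", neuron_partition(joint))

jg.confidences = ConfidenceFactors(1, 0, 0, 0)  # neuron evidence only
neuron_only = gaec_solve(jg)
print("neuron-only solve:", neuron_partition(neuron_only))

print("ground truth     :", sorted(sorted(c) for c in ground_truth))
print("The joint model returns the true chains {1,2,3} and {4,5,6}; the "
      "neuron-only multicut splits node 1 off and merges the two chains.")
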