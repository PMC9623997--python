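# Methods

## The joint partitioning model

`jointcut` phrases simultaneous reconstruction of neurons, mitochondria
and synapses as one multicut (correlation clustering) problem. Every 2D
region — a neuron superpixel, a mitochondrion cross-section, a pre- or
post-synaptic region — is a node; edges carry real weights whose sign
encodes attraction or repulsion; and a solution is a decomposition of the
graph into connected components, each component one 3D instance. The cost
of a solution is the total weight of cut edges, with each of the four edge
classes (neuron, mitochondria, synapse, affiliation) scaled by a
confidence factor λ; the four factors lie in [0, 1] and sum to 1. Cycle
consistency (no cycle crosses the cut exactly once) guarantees the edge
labeling is induced by a node partition; the solver enforces it by
construction, and `is_valid_partition_solution` checks it for arbitrary
edge labelings via connected components of the join edges — equivalent to
cycle enumeration but polynomial.

The model's assumptions, and where they come from:

* **Over-segmentation only.** Superpixels never span two neurons;
  under-segmentation must be avoided upstream (at the watershed stage).
  The solver can only merge fragments, never split them.
* **Link consensus.** A 3D mitochondrion lies inside exactly one neuron,
  so mitochondria-to-mitochondria links and mitochondria-to-neuron
  affiliations transfer connectivity evidence onto the neuron graph.
* **Not-link consensus.** A synapse's pre- and post-side lie in different
  neurons, so each pre/post pair contributes one repulsive edge.
* **Aligned stack.** Regions on different slices are compared by their
  in-plane (y, x) footprints; no registration is modelled.

## Edge weights

Merge probabilities are converted to weights by the biased log-odds
transform `w = logit(p) + log((1-β)/β)`, with p clipped to
`[1e-6, 1 - 1e-6]` because semantic maps contain exact 0/1 responses.
The stored probability is always the *merge* probability (probability the
endpoints belong to the same object), so positive weight means attraction;
β > 0.5 biases a class toward splitting, β < 0.5 toward merging, and at
the default β = 0.5 the transform is the plain logit. Each edge class has
its own β (all default 0.5); they matter mostly when the semantic maps for
one structure are systematically better or worse than the others, and can
be tuned with the `tune` grid-search helper together with λ.

Per class:

* **Neuron** (`build_neuron_rag`): the RAG joins 4-adjacent superpixels
  within a slice (plane-axis edges) and vertically overlapping superpixels
  on adjacent slices (cutting-axis edges). For every contact pixel pair
  the membrane response is averaged over the two pixels;
  `p = 1 - mean` over the interface. 4-connectivity and ≥ 1 voxel of
  vertical overlap are the conventional RAG choices. A user-supplied
  per-edge probability source (e.g. a learned edge classifier) can replace
  the mean-affinity path by rebuilding the graph from its own
  probabilities — `corrupt_edge_probabilities` in the synthetic pipeline
  is exactly such a source.
* **Mitochondria / within-class synapse** (`build_mitochondria_graph`,
  `build_synapse_graph`): candidate links join regions at most
  `slice_gap` (default 2) slices apart with positive IoU similarity
  `(D + λ_iou·S) / (1 + λ_iou)`, where D is bounding-box IoU and S pixel-mask
  IoU, both in-plane. `λ_iou` defaults to 1 (equal weight); the similarity
  is the merge probability, so these edges are never repulsive.
* **Pre/post repulsion**: one repulsive edge per listed (pre, post) region
  pair, with merge probability `prepost_repulsion_prob` (default 0.1,
  weight −ln 9 at β = 0.5). The magnitude is a modelling choice: strong
  enough to veto a single wrong attractive neuron edge at equal
  confidences, weak enough to be overruled by consistent evidence.
* **Affiliation** (`build_affiliation_edges`): a neuron region and an
  ultrastructure region on the *same slice* are linked when their pixel
  overlap exceeds `area_threshold`; p is the mean semantic-map response
  over the overlap (the mean, not the raw sum, keeps p in [0, 1]). The
  threshold suppresses spurious links from detection noise; 50 px suits
  full-resolution EM regions, while the synthetic pipeline uses 10 px
  because its regions are an order of magnitude smaller.

## Solver

GAEC starts from singletons and repeatedly contracts the edge with the
largest positive effective (λ-scaled) weight; parallel edges arising from
a contraction are merged by summation (sum linkage). Termination is
strict: zero-weight edges are *not* contracted (configurable), since zero
evidence should not force a merge. The implementation uses a lazy-deletion
binary heap with stale-entry skipping plus union-find with path
compression; supernodes are represented by their smallest member id and
ties break toward the lexicographically smallest (min id, max id) pair, so
the solver is deterministic. Each contraction lowers the objective by the
contracted weight; the recorded trace is therefore monotone
non-increasing and is asserted in tests. Effective weights are baked in at
assembly, making the solver class-agnostic.

The exact oracle (`brute_force_solve`) enumerates all set partitions as
restricted growth strings and evaluates the objective for all partitions
vectorised; ties break toward fewer components, then lexicographically.
It refuses more than 12 nodes (Bell(12) ≈ 4.2 M) and exists purely to
certify the heuristic. `cc_labeling_3d` (26-connectivity components via
`scipy.ndimage.label`) is the classical ultrastructure baseline.

## Post-processing

Component labels restricted to one structure give that structure's
instance labeling (labels renumbered from 1, background 0). Because
ultrastructure nodes can share a component purely through neuron-level
paths (two mitochondria in one neuron), any label class that is
disconnected in its own structure graph is split: the component containing
the smallest node id keeps the label, the others get fresh labels,
iterating until every class is connected. The result is a refinement of
the input labeling and the operation is idempotent; the processing order
of violating labels does not affect the final partition (asserted by
test). Because splitting discards the intentional co-assignment signal
(e.g. multi-contact synapses), `multi_contact_report` lists the affected
label classes before splitting.

## Metrics

Variation of information is computed from the sparse joint contingency
table of the two labelings in log base 2 (bits; the base is a pure
rescaling). `vi_split = H(S|T)` measures over-segmentation and
`vi_merge = H(T|S)` under-segmentation, with S the reconstruction and T
the gold standard. Voxels with T = 0 (gold background) are excluded;
S = 0 voxels are kept unless the caller masks them, and an optional voxel
mask implements region-restricted variants (e.g. only fragments
overlapping ultrastructure). Adapted Rand error is `1 − F1` of
pair-counting precision and recall computed from squared contingency sums
*without* subtracting the diagonal — the SNEMI evaluation-script
convention; implementations that subtract it (counting unordered pixel
pairs only) give systematically different values on small inputs, which
the test suite accounts for when cross-checking against scikit-image.

## Synthetic volumes

The generator reproduces the geometry the model reasons about, not EM
appearance. Defaults, chosen once as the study conditions: an
8 × 64 × 64 (z, y, x) stack; 3 neurons as z-extruded y-bands whose mutual
boundaries jitter by ±1 row per slice (anisotropy and imperfect
alignment); 3 mitochondria (7 × 7 in-plane, spanning ≥ 2 and typically
most slices, strictly inside one neuron with 2-row margins); 2 synapse
pairs, each a 3 × 5 pre region and its post region mirrored across a
neuron boundary on two shared slices; 3 fragments per neuron cross-section
(geodesic watershed from random seeds, a strict refinement of the neuron
labels). Ultrastructure objects occupy disjoint x-slots so that no two
instances generate spurious IoU links.

Neuron edge unreliability is modelled at the edge level, where the
model's failure mode lives: each RAG edge gets the ideal merge probability
0.9 (same neuron) or 0.1 (different neurons) — symmetric ±ln 9 weights at
β = 0.5 — flipped across 0.5 with probability ε (default 0.2) and jittered
uniformly by ±0.05. Voxel-level degradation enters only through the
semantic maps (per-slice Gaussian blur plus Gaussian noise, clipped to
[0, 1]). Every generator is a pure function of (spec, seed).

What passing tests on these volumes do show: the solver, graph
construction, post-processing and metrics are correct end to end; exact
recovery holds when the inputs are clean; and ultrastructure evidence
measurably repairs corrupted neuron cues under controlled noise. What
they do not show: robustness to real EM texture, misalignment beyond ±1
px, semantic-segmentation errors (false or missing ultrastructure
detections), under-segmented superpixels, or neuron geometries with
branching and wrapping — all of which affect real data.

## Numerical choices and problem sizes

Probabilities are clipped at 1e-6 before the logit; confidence factors
must sum to 1 within 1e-9; brute-force ties resolve toward fewer
components then lexicographic labels; GAEC tie-breaks are documented
above; degenerate inputs (empty graphs, empty structures, all-background
volumes) return empty results rather than erroring, while genuinely
contradictory inputs (overlapping regions, id collisions, out-of-range
probabilities) raise typed errors.

The bundled verification runs at desk scale: the solver-vs-oracle suite
uses 200 random graphs of 4–10 nodes; the consensus comparison uses 50
seeded volumes of 8 × 64 × 64 voxels (~100-node joint graphs); the
scaling check solves a 10⁴-node / 5·10⁴-edge random signed graph, which
completes in about a second. Larger volumes are limited mainly by the
per-slice Python loops in region extraction and by GAEC's heap, both of
which scale to the 10⁵–10⁶-edge range comfortably.

## Known limitations

* Long-range (lifted) edges are not modelled; evidence only flows along
  chains of local edges.
* No LP relaxation or lower bound: GAEC is a heuristic, and its gap to
  the optimum is certified only on enumerable instances.
* The neuron similarity path implemented is mean membrane affinity;
  learned edge classifiers must be supplied externally as per-edge
  probabilities.
* Affiliation edges are same-slice only, consistent with planar overlap;
  heavily tilted structures may need cross-slice affiliations.
* The pre/post pairing is an input; deriving it from a union semantic map
  is supported only through per-slice connected components containing one
  region of each side.
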