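import math

import numpy as np
import pytest

from jointcut.core import (
    ConfidenceFactors,
    EdgeClass,
    LabelVolume,
    ProbabilityVolume,
    Region,
    SignedGraph,
    Structure,
)
from jointcut.graphs import (
    GraphBuildConfig,
    assemble_joint_graph,
    build_affiliation_edges,
    build_mitochondria_graph,
    build_neuron_rag,
    build_synapse_graph,
    extract_regions,
    generate_superpixels,
    iou_similarity,
)


def square_region(rid, structure, z, y0, x0, h, w, label=1):
    ys, xs = np.mgrid[y0 : y0 + h, x0 : x0 + w]
    return Region(
        id=rid,
        structure=structure,
        slice_index=z,
        mask=np.stack([ys.ravel(), xs.ravel()], axis=1),
        source_label=label,
    )


class TestExtractRegions:
    def test_empty_volume(self):
        vol = LabelVolume(np.zeros((3, 4, 4), dtype=np.int64))
        assert extract_regions(vol, Structure.NEURON) == []

    def test_single_square(self):
        data = np.zeros((5, 10, 10), dtype=np.int64)
        data[3, 2:7, 1:6] = 7
        regions = extract_regions(LabelVolume(data), Structure.MITOCHONDRION)
        assert len(regions) == 1
        r = regions[0]
        assert r.area == 25 and r.slice_index == 3 and r.source_label == 7
        assert r.bbox == (2, 1, 7, 6)

    def test_diagonally_touching_labels_stay_distinct(self):
        data = np.zeros((1, 4, 4), dtype=np.int64)
        data[0, 0, 0] = 1
        data[0, 1, 1] = 2
        regions = extract_regions(LabelVolume(data), Structure.NEURON)
        assert len(regions) == 2

    def test_same_label_on_two_slices_gives_two_regions(self):
        data = np.zeros((2, 4, 4), dtype=np.int64)
        data[:, 1:3, 1:3] = 5
        regions = extract_regions(LabelVolume(data), Structure.MITOCHONDRION, id_start=10)
        assert [r.id for r in regions] == [10, 11]
        with pytest.raises(ValueError):
            extract_regions(LabelVolume(data), Structure.NEURON, ids_from_labels=True)


class TestSuperpixels:
    def test_constant_slice_yields_one_superpixel_each(self):
        boundary = ProbabilityVolume(np.zeros((3, 16, 16)))
        sp = generate_superpixels(boundary)
        for z in range(3):
            assert len(np.unique(sp.data[z])) == 1

    def test_ridge_bisects_slice(self):
        data = np.zeros((1, 16, 16))
        data[0, :, 8] = 1.0
        sp = generate_superpixels(ProbabilityVolume(data), smoothing_sigma=0.8)
        left = sp.data[0, :, :6]
        right = sp.data[0, :, 10:]
        assert len(np.unique(sp.data[0])) >= 2
        assert not set(np.unique(left)) & set(np.unique(right))

    def test_labels_disjoint_across_slices(self):
        rng = np.random.default_rng(2)
        boundary = ProbabilityVolume(rng.random((4, 20, 20)))
        sp = generate_superpixels(boundary)
        seen = set()
        for z in range(4):
            labels = set(np.unique(sp.data[z]).tolist())
            assert not labels & seen
            seen |= labels


class TestNeuronRag:
    def two_superpixel_volume(self, boundary_value):
        sp = np.zeros((1, 4, 8), dtype=np.int64)
        sp[0, :, :4] = 1
        sp[0, :, 4:] = 2
        bd = np.full((1, 4, 8), float(boundary_value))
        return LabelVolume(sp), ProbabilityVolume(bd)

    def test_clear_interface_attracts(self):
        sp, bd = self.two_superpixel_volume(0.0)
        g = build_neuron_rag(sp, bd, GraphBuildConfig())
        ((w, p),) = g.edges.values()
        assert p == pytest.approx(1.0)
        assert w > 10  # clipped logit of ~1

    def test_membrane_interface_repels(self):
        sp, bd = self.two_superpixel_volume(1.0)
        g = build_neuron_rag(sp, bd, GraphBuildConfig())
        ((w, p),) = g.edges.values()
        assert p == pytest.approx(0.0)
        assert w < -10

    def test_interface_means_map_to_log_odds(self):
        # three side-by-side superpixels; interfaces at mean 0.2 and 0.8
        sp = np.zeros((1, 2, 6), dtype=np.int64)
        sp[0, :, :2], sp[0, :, 2:4], sp[0, :, 4:] = 1, 2, 3
        bd = np.zeros((1, 2, 6))
        bd[0, :, 1:3] = 0.2  # both sides of interface 1|2
        bd[0, :, 3:5] = 0.8
        g = build_neuron_rag(LabelVolume(sp), ProbabilityVolume(bd), GraphBuildConfig())
        assert g.edges[(1, 2)][0] == pytest.approx(math.log(4))  # p=0.8
        assert g.edges[(2, 3)][0] == pytest.approx(-math.log(4))  # p=0.2

    def test_cutting_axis_edges_from_vertical_overlap(self):
        sp = np.zeros((2, 4, 4), dtype=np.int64)
        sp[0] = 1
        sp[1] = 2
        bd = np.zeros((2, 4, 4))
        g = build_neuron_rag(LabelVolume(sp), ProbabilityVolume(bd), GraphBuildConfig())
        assert (1, 2) in g.edges

    def test_shape_mismatch_raises(self):
        sp, _ = self.two_superpixel_volume(0.0)
        with pytest.raises(ValueError):
            build_neuron_rag(sp, ProbabilityVolume(np.zeros((1, 4, 9))), GraphBuildConfig())

    def test_interface_means_match_brute_force_pixel_scan(self):
        rng = np.random.default_rng(4)
        sp_data = rng.integers(1, 5, size=(2, 8, 8)).astype(np.int64)
        sp_data[1] += 4  # labels unique per slice
        bd_data = rng.random((2, 8, 8))
        g = build_neuron_rag(LabelVolume(sp_data), ProbabilityVolume(bd_data), GraphBuildConfig())
        # oracle: scan every 4-neighbour / vertical pixel pair directly
        sums, counts = {}, {}

        def visit(la, lb, va, vb):
            if la != lb and la > 0 and lb > 0:
                e = (min(la, lb), max(la, lb))
                sums[e] = sums.get(e, 0.0) + 0.5 * (va + vb)
                counts[e] = counts.get(e, 0) + 1

        for z in range(2):
            for y in range(8):
                for x in range(8):
                    if x + 1 < 8:
                        visit(sp_data[z, y, x], sp_data[z, y, x + 1], bd_data[z, y, x], bd_data[z, y, x + 1])
                    if y + 1 < 8:
                        visit(sp_data[z, y, x], sp_data[z, y + 1, x], bd_data[z, y, x], bd_data[z, y + 1, x])
                    if z == 0:
                        visit(sp_data[0, y, x], sp_data[1, y, x], bd_data[0, y, x], bd_data[1, y, x])
        assert set(g.edges) == set(sums)
        for e in sums:
            assert g.edges[e][1] == pytest.approx(1.0 - sums[e] / counts[e])


class TestIouSimilarity:
    def test_identical_regions_give_one(self):
        u = square_region(1, Structure.MITOCHONDRION, 0, 2, 2, 4, 4)
        v = square_region(2, Structure.MITOCHONDRION, 1, 2, 2, 4, 4)
        for lam in (0.0, 0.5, 1.0, 3.0):
            assert iou_similarity(u, v, lam) == pytest.approx(1.0)

    def test_disjoint_bboxes_give_zero(self):
        u = square_region(1, Structure.MITOCHONDRION, 0, 0, 0, 2, 2)
        v = square_region(2, Structure.MITOCHONDRION, 1, 5, 5, 2, 2)
        assert iou_similarity(u, v, 1.0) == 0.0

    def test_hand_computed_blend(self):
        # u: full 10-px row; v: pixels {0,1,9} of the same row on the next
        # slice -> bbox IoU 1.0, mask IoU 3/10; at lambda=1 blend = 0.65
        u = square_region(1, Structure.MITOCHONDRION, 0, 0, 0, 1, 10)
        v = Region(
            id=2,
            structure=Structure.MITOCHONDRION,
            slice_index=1,
            mask=np.array([[0, 0], [0, 1], [0, 9]]),
        )
        assert iou_similarity(u, v, 1.0) == pytest.approx((1.0 + 0.3) / 2)
        assert iou_similarity(u, v, 0.0) == pytest.approx(1.0)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            u = square_region(1, Structure.MITOCHONDRION, 0, *rng.integers(0, 6, 2), *rng.integers(1, 5, 2))
            v = square_region(2, Structure.MITOCHONDRION, 1, *rng.integers(0, 6, 2), *rng.integers(1, 5, 2))
            s1 = iou_similarity(u, v, 1.0)
            assert s1 == pytest.approx(iou_similarity(v, u, 1.0))
            assert 0.0 <= s1 <= 1.0


class TestMitochondriaGraph:
    def test_aligned_blobs_one_slice_apart(self):
        regions = [
            square_region(1, Structure.MITOCHONDRION, 0, 2, 2, 3, 3),
            square_region(2, Structure.MITOCHONDRION, 1, 2, 2, 3, 3),
        ]
        g = build_mitochondria_graph(regions, GraphBuildConfig())
        assert set(g.edges) == {(1, 2)}
        assert g.edges[(1, 2)][1] == pytest.approx(1.0)

    def test_slice_gap_filter(self):
        regions = [
            square_region(1, Structure.MITOCHONDRION, 0, 2, 2, 3, 3),
            square_region(2, Structure.MITOCHONDRION, 3, 2, 2, 3, 3),
        ]
        g = build_mitochondria_graph(regions, GraphBuildConfig(slice_gap=2))
        assert g.n_edges == 0

    def test_chain_of_five_has_seven_edges(self):
        regions = [square_region(i, Structure.MITOCHONDRION, i, 2, 2, 3, 3) for i in range(5)]
        g = build_mitochondria_graph(regions, GraphBuildConfig(slice_gap=2))
        # 4 consecutive + 3 skip-one pairs
        assert g.n_edges == 7

    def test_wrong_structure_rejected(self):
        with pytest.raises(ValueError):
            build_mitochondria_graph(
                [square_region(1, Structure.NEURON, 0, 0, 0, 2, 2)], GraphBuildConfig()
            )


class TestSynapseGraph:
    def make_stacks(self):
        pre = [
            square_region(1, Structure.PRE_SYNAPSE, 0, 0, 0, 2, 3),
            square_region(2, Structure.PRE_SYNAPSE, 1, 0, 0, 2, 3),
        ]
        post = [
            square_region(3, Structure.POST_SYNAPSE, 0, 6, 0, 2, 3),
            square_region(4, Structure.POST_SYNAPSE, 1, 6, 0, 2, 3),
        ]
        return pre, post

    def test_fixture_edge_counts(self):
        pre, post = self.make_stacks()
        g = build_synapse_graph(pre, post, [(1, 3)], GraphBuildConfig())
        attractive = [e for e, (w, _p) in g.edges.items() if w > 0]
        repulsive = [e for e, (w, _p) in g.edges.items() if w < 0]
        assert len(attractive) == 2 and repulsive == [(1, 3)]

    def test_no_pairs_no_repulsion(self):
        pre, post = self.make_stacks()
        g = build_synapse_graph(pre, post, [], GraphBuildConfig())
        assert all(w > 0 for w, _p in g.edges.values())

    def test_repulsive_weight_value(self):
        pre, post = self.make_stacks()
        g = build_synapse_graph(pre, post, [(1, 3)], GraphBuildConfig(prepost_repulsion_prob=0.1))
        assert g.edges[(1, 3)][0] == pytest.approx(-math.log(9))

    def test_unknown_region_in_pair_raises(self):
        pre, post = self.make_stacks()
        with pytest.raises(KeyError):
            build_synapse_graph(pre, post, [(1, 99)], GraphBuildConfig())


class TestDerivePairs:
    def build(self, union_rows):
        pre = np.zeros((1, 12, 6), dtype=np.int64)
        pre[0, 2:4, 1:4] = 1
        post = np.zeros((1, 12, 6), dtype=np.int64)
        post[0, 6:8, 1:4] = 1
        union = np.zeros((1, 12, 6), dtype=np.int64)
        union[0, union_rows, 1:4] = 1
        from jointcut.graphs import derive_synapse_pairs

        pres = extract_regions(LabelVolume(pre), Structure.PRE_SYNAPSE, id_start=1)
        posts = extract_regions(LabelVolume(post), Structure.POST_SYNAPSE, id_start=10)
        return derive_synapse_pairs(pres, posts, LabelVolume(union))

    def test_shared_component_pairs_pre_with_post(self):
        assert self.build(slice(2, 8)) == [(1, 10)]

    def test_disconnected_union_components_do_not_pair(self):
        # union covers each side separately but not the gap between them
        pre_only = np.r_[2:4]
        post_only = np.r_[6:8]
        assert self.build(np.concatenate([pre_only, post_only])) == []


class TestAffiliationEdges:
    def setup_regions(self, overlap_h, overlap_w, prob_value):
        neuron = square_region(1, Structure.NEURON, 0, 0, 0, 20, 20)
        ultra = square_region(10, Structure.MITOCHONDRION, 0, 0, 0, overlap_h, overlap_w)
        prob = ProbabilityVolume(np.full((1, 20, 20), prob_value), channel="mitochondria")
        return [neuron], [ultra], prob

    def test_below_area_threshold_no_edge(self):
        n, u, p = self.setup_regions(5, 8, 0.8)  # overlap 40 px
        assert build_affiliation_edges(n, u, p, GraphBuildConfig(area_threshold=50)) == []

    def test_above_threshold_mean_probability(self):
        n, u, p = self.setup_regions(10, 10, 0.8)  # overlap 100 px
        edges = build_affiliation_edges(n, u, p, GraphBuildConfig(area_threshold=50))
        ((e, w, pm),) = edges
        assert e == (1, 10) and pm == pytest.approx(0.8)
        assert w == pytest.approx(math.log(4))

    def test_full_containment_max_weight(self):
        n, u, p = self.setup_regions(10, 10, 1.0)
        ((_e, w, pm),) = build_affiliation_edges(n, u, p, GraphBuildConfig(area_threshold=50))
        assert pm == pytest.approx(1.0)
        assert w > 10

    def test_different_slice_no_edge(self):
        neuron = square_region(1, Structure.NEURON, 0, 0, 0, 20, 20)
        ultra = square_region(10, Structure.MITOCHONDRION, 1, 0, 0, 10, 10)
        prob = ProbabilityVolume(np.ones((2, 20, 20)))
        assert build_affiliation_edges([neuron], [ultra], prob, GraphBuildConfig()) == []


class TestAssemble:
    def small_parts(self):
        neuron_g = SignedGraph()
        neuron_g.add_edge(1, 2, 1.0, 0.7)
        mito_g = SignedGraph()
        mito_g.add_edge(10, 11, 2.0, 0.9)
        syn_g = SignedGraph()
        syn_g.add_edge(20, 21, -2.0, 0.1)
        affiliation = [((1, 10), 1.5, 0.8), ((2, 20), 1.5, 0.8)]
        return neuron_g, mito_g, syn_g, affiliation

    def test_degenerate_neuron_only_is_multicut(self):
        neuron_g = SignedGraph()
        neuron_g.add_edge(1, 2, 1.0)
        jg = assemble_joint_graph(neuron_g, SignedGraph(), SignedGraph(), [], ConfidenceFactors(1, 0, 0, 0))
        assert jg.graph.n_edges == 1
        assert jg.effective_weight(1, 2) == 1.0

    def test_edge_count_is_sum_of_parts(self):
        ng, mg, sg, aff = self.small_parts()
        jg = assemble_joint_graph(ng, mg, sg, aff, ConfidenceFactors())
        assert jg.graph.n_edges == ng.n_edges + mg.n_edges + sg.n_edges + len(aff)
        classes = set(jg.edge_class.values())
        assert classes == {EdgeClass.NEURON, EdgeClass.MITO, EdgeClass.SYN, EdgeClass.AFFILIATION}

    def test_affiliation_edges_join_neuron_and_ultra(self):
        ng, mg, sg, aff = self.small_parts()
        jg = assemble_joint_graph(ng, mg, sg, aff, ConfidenceFactors())
        for e, klass in jg.edge_class.items():
            if klass is EdgeClass.AFFILIATION:
                groups = {jg.node_group[e[0]], jg.node_group[e[1]]}
                assert "neuron" in groups and groups != {"neuron"}

    def test_id_collision_raises(self):
        ng, mg, sg, aff = self.small_parts()
        mg.add_node(1)
        with pytest.raises(ValueError):
            assemble_joint_graph(ng, mg, sg, aff, ConfidenceFactors())

    def test_invalid_confidences_raise(self):
        ng, mg, sg, aff = self.small_parts()
        with pytest.raises(Exception):
            assemble_joint_graph(ng, mg, sg, aff, ConfidenceFactors(0.5, 0.5, 0.5, 0.5))

    def test_bad_affiliation_endpoint_raises(self):
        ng, mg, sg, _aff = self.small_parts()
        with pytest.raises(ValueError):
            assemble_joint_graph(ng, mg, sg, [((10, 11), 1.0, 0.9)], ConfidenceFactors())
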