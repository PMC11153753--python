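import copy
import warnings

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from fetalfold.geometry import mean_curvature, smooth_vertex_field
from fetalfold.pattern import (
    BasinGraph,
    FeatureWeights,
    basin_features,
    build_basin_graph,
    load_basin_graph,
    save_basin_graph,
    similarity_index,
    spectral_match,
    watershed_basins,
)
from fetalfold.synthetic import Pit, fibonacci_directions, synth_surface


def negative_component_count(mesh, smooth_iters=10):
    """Oracle: connected components of the {smoothed H < 0} vertex set."""
    sm = smooth_vertex_field(mean_curvature(mesh), smooth_iters)
    neg = np.nonzero(sm.values < 0)[0]
    if len(neg) == 0:
        return 0
    pos = {v: i for i, v in enumerate(neg)}
    edges = mesh.edges()
    rows, cols = [], []
    for a, b in edges:
        if a in pos and b in pos:
            rows.append(pos[a])
            cols.append(pos[b])
    g = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(neg), len(neg))
    )
    n, _ = connected_components(g, directed=False)
    return n


def pit_phantom(k: int):
    dirs = fibonacci_directions(k)
    pits = tuple(Pit(d, 3.0, 2.0) for d in dirs)
    return synth_surface(20.0, radius=10.0, amplitude=0.0, pits=pits)


class TestWatershed:
    def test_convex_sphere_has_no_basins(self, icosphere4):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph, labels = watershed_basins(
                icosphere4, mean_curvature(icosphere4), 10, 0.0
            )
        assert graph.n == 0
        assert np.all(labels == -1)

    @pytest.mark.parametrize("k", [1, 3, 6])
    def test_k_pits_give_k_basins(self, k):
        mesh, truth = pit_phantom(k)
        graph, labels = watershed_basins(mesh, mean_curvature(mesh), 10, 0.0)
        assert graph.n == k
        # each pit bottom falls in a distinct basin
        bottoms = {labels[v] for v in truth["pit_vertices"]}
        assert len(bottoms) == k

    def test_infinite_merge_equals_connected_components(self):
        mesh, _ = synth_surface(30.0, seed=11)
        graph, _ = watershed_basins(mesh, mean_curvature(mesh), 10, np.inf)
        assert graph.n == negative_component_count(mesh)

    def test_basins_partition_sulcal_set(self):
        mesh, _ = synth_surface(30.0, seed=11)
        curv = mean_curvature(mesh)
        graph, labels = watershed_basins(mesh, curv, 10, 0.0)
        sm = smooth_vertex_field(curv, 10)
        assert np.array_equal(labels >= 0, sm.values < 0)
        all_members = np.concatenate([b.vertices for b in graph.basins])
        assert len(all_members) == len(set(all_members.tolist()))


class TestBasinFeatures:
    def _graph(self, mesh):
        return build_basin_graph(mesh, spacing=1.5, merge_ridge=0.02)

    def test_uniform_scaling_leaves_features_unchanged(self):
        from fetalfold.mesh import TriMesh
        from fetalfold.morphometry import hull_surface, sulcal_depth

        mesh, _ = synth_surface(30.0, seed=8)
        curv = mean_curvature(mesh)
        big = TriMesh(mesh.vertices * 2.0, mesh.faces, closed=True)

        # merge_ridge is in curvature units (1/mm), so only the unmerged
        # watershed is scale-free; basins then coincide exactly
        g1, _ = watershed_basins(mesh, curv, 10, 0.0)
        g2, _ = watershed_basins(big, mean_curvature(big), 10, 0.0)
        h1 = hull_surface(mesh, 1.5)
        h2 = hull_surface(big, 3.0)  # same relative resolution
        basin_features(g1, mesh, sulcal_depth(mesh, h1, 1.5))
        basin_features(g2, big, sulcal_depth(big, h2, 3.0))
        f1, f2 = g1.feature_matrix(), g2.feature_matrix()
        assert f1.shape == f2.shape
        np.testing.assert_allclose(f1[:, :3], f2[:, :3], atol=1e-6)  # position
        np.testing.assert_allclose(f1[:, 4], f2[:, 4], atol=1e-9)  # area

    def test_normalized_basin_areas_bounded(self):
        mesh, _ = synth_surface(30.0, seed=8)
        graph = self._graph(mesh)
        total = sum(b.norm_area for b in graph.basins)
        assert 0 < total <= 1.0

    def test_single_pit_centroid_on_pit_axis(self):
        mesh, truth = pit_phantom(1)
        graph = build_basin_graph(mesh, spacing=0.75, merge_ridge=0.0)
        assert graph.n == 1
        c = graph.basins[0].centroid
        axis = fibonacci_directions(1)[0]
        cosang = np.dot(c / np.linalg.norm(c), axis)
        assert cosang > 0.99


class TestSpectralMatch:
    def test_template_self_match_is_identity(self, template29):
        _, graph, _ = template29
        m = spectral_match(graph, graph)
        assert len(m.pairs) == graph.n
        assert all(s == t for s, t in m.pairs)

    def test_recovers_random_id_permutation(self, template29):
        _, graph, _ = template29
        rng = np.random.default_rng(3)
        perm = rng.permutation(graph.n)
        basins = [copy.deepcopy(graph.basins[i]) for i in perm]
        idmap = {}
        for new_id, b in enumerate(basins):
            idmap[b.id] = new_id
            b.id = new_id
        edges = {
            (min(idmap[a], idmap[b]), max(idmap[a], idmap[b]))
            for a, b in graph.edges
        }
        permuted = BasinGraph(basins, edges)
        m = spectral_match(permuted, graph)
        assert len(m.pairs) == graph.n
        assert all(idmap[t] == s for s, t in m.pairs)

    def test_robust_to_centroid_jitter(self, template29):
        """>= 90% of basins match their originators under sigma=0.02 jitter."""
        _, graph, _ = template29
        correct = total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            jittered = BasinGraph(
                [copy.deepcopy(b) for b in graph.basins], set(graph.edges)
            )
            for b in jittered.basins:
                b.centroid = b.centroid + rng.normal(0, 0.02, 3)
            m = spectral_match(jittered, graph)
            correct += sum(s == t for s, t in m.pairs)
            total += graph.n
        assert correct / total >= 0.90

    def test_empty_graph_rejected(self, template29):
        _, graph, _ = template29
        with pytest.raises(ValueError):
            spectral_match(BasinGraph([], set()), graph)


class TestSimilarityIndex:
    def test_self_similarity_is_one_everywhere(self, template29):
        _, graph, _ = template29
        m = spectral_match(graph, graph)
        rec = similarity_index(m, graph, graph)
        for scope in (rec.corresponding, rec.inter_sulcal, rec.whole_pattern):
            for v in scope.values():
                assert v == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_weights_reduce_to_single_feature(self, template29):
        _, graph, _ = template29
        sub = BasinGraph(
            [copy.deepcopy(b) for b in graph.basins], set(graph.edges)
        )
        rng = np.random.default_rng(0)
        for b in sub.basins:
            b.centroid = b.centroid + rng.normal(0, 0.01, 3)
            b.mean_depth = min(1.0, b.mean_depth + abs(rng.normal(0, 0.02)))
        w = FeatureWeights(1.0, 0.0, 0.0)
        m = spectral_match(sub, graph, w)
        rec = similarity_index(m, sub, graph, w)
        assert rec.whole_pattern["combined"] == pytest.approx(
            rec.whole_pattern["position"], abs=1e-12
        )

    def test_area_perturbation_isolated_to_area_feature(self, template29):
        _, graph, _ = template29
        sub = BasinGraph(
            [copy.deepcopy(b) for b in graph.basins], set(graph.edges)
        )
        for b in sub.basins:
            b.norm_area = b.norm_area + 0.2 / graph.n  # +20% of total in sum
        m = spectral_match(sub, graph)
        rec = similarity_index(m, sub, graph)
        discount = 2 * len(m.pairs) / (sub.n + graph.n)
        assert rec.whole_pattern["depth"] == pytest.approx(discount, abs=1e-9)
        assert rec.whole_pattern["position"] == pytest.approx(discount, abs=1e-9)
        assert rec.whole_pattern["area"] < rec.whole_pattern["depth"]

    def test_symmetric_in_subject_and_template(self, template29):
        _, graph, _ = template29
        sub = BasinGraph(
            [copy.deepcopy(b) for b in graph.basins], set(graph.edges)
        )
        rng = np.random.default_rng(5)
        for b in sub.basins:
            b.centroid = b.centroid + rng.normal(0, 0.02, 3)
        m_ab = spectral_match(sub, graph)
        m_ba = spectral_match(graph, sub)
        r_ab = similarity_index(m_ab, sub, graph)
        r_ba = similarity_index(m_ba, graph, sub)
        for f in ("position", "depth", "area", "combined"):
            assert r_ab.whole_pattern[f] == pytest.approx(
                r_ba.whole_pattern[f], abs=1e-9
            )

    def test_unmatched_basins_discount_whole_pattern(self, template29):
        _, graph, _ = template29
        sub = BasinGraph(
            [copy.deepcopy(b) for b in graph.basins[:-2]],
            {e for e in graph.edges if e[0] < graph.n - 2 and e[1] < graph.n - 2},
        )
        m = spectral_match(sub, graph)
        rec = similarity_index(m, sub, graph)
        expected = 2 * len(m.pairs) / (sub.n + graph.n)
        assert rec.whole_pattern["position"] <= expected + 1e-9
        assert rec.whole_pattern["position"] < 1.0

    def test_inter_sulcal_invariant_to_rigid_translation(self, template29):
        _, graph, _ = template29
        sub = BasinGraph(
            [copy.deepcopy(b) for b in graph.basins], set(graph.edges)
        )
        for b in sub.basins:
            b.centroid = b.centroid + np.array([0.05, -0.02, 0.03])
        # the property concerns the difference-of-differences form itself,
        # so pin the correspondence to the identity matching
        from fetalfold.pattern import Matching

        m = Matching([(i, i) for i in graph.basin_ids()], [], [])
        rec = similarity_index(m, sub, graph)
        assert rec.inter_sulcal["position"] == pytest.approx(1.0, abs=1e-9)
        assert rec.corresponding["position"] < 1.0

    def test_si_bounded_and_json_round_trip(self, template29, tmp_path):
        _, graph, _ = template29
        m = spectral_match(graph, graph)
        rec = similarity_index(m, graph, graph)
        d = rec.as_dict()
        for scope in ("corresponding_regions", "inter_sulcal", "whole_pattern"):
            for v in d[scope].values():
                assert 0.0 <= v <= 1.0
        save_basin_graph(graph, tmp_path / "g.json")
        back = load_basin_graph(tmp_path / "g.json")
        assert back.n == graph.n
        assert back.edges == graph.edges
        np.testing.assert_allclose(
            back.feature_matrix(), graph.feature_matrix(), rtol=1e-12
        )
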