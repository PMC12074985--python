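"""TEASAR skeletons: tree property, branch/spur handling, attachment."""

import networkx as nx
import numpy as np
import pytest

import microcave as mc
from microcave.errors import InvalidArgumentError
from microcave.skeleton import (attach_annotations, attach_features,
                                build_weighted_l2_graph, teasar, write_swc,
                                skeletonize_root)
from microcave.l2cache import L2Cache

from conftest import tube_volume, random_edits


def graph_from_coords(edges, coords):
    g = nx.Graph()
    for n, c in coords.items():
        g.add_node(n, coord=np.asarray(c, dtype=float))
    for u, v in edges:
        g.add_edge(u, v, weight=float(np.linalg.norm(
            np.asarray(coords[u]) - np.asarray(coords[v]))))
    return g


def path_graph(n, pitch=10.0):
    coords = {i: (i * pitch, 0.0, 0.0) for i in range(n)}
    return graph_from_coords([(i, i + 1) for i in range(n - 1)], coords)


def y_graph(arm=5, pitch=10.0):
    """Three arms of `arm` edges meeting at a hub (node 0)."""
    coords = {0: (0.0, 0.0, 0.0)}
    edges = []
    n = 1
    for direction in [(1, 0, 0), (-1, 0, 0), (0, 1, 0)]:
        prev = 0
        for i in range(1, arm + 1):
            coords[n] = tuple(pitch * i * d for d in direction)
            edges.append((prev, n))
            prev = n
            n += 1
    return graph_from_coords(edges, coords)


def test_single_vertex_degenerate():
    g = graph_from_coords([], {7: (1.0, 2.0, 3.0)})
    s = teasar(g, (0, 0, 0), d=5.0)
    assert s.n_vertices == 1 and s.edges == []
    assert s.invalidation_map == {7: 0}
    assert s.is_tree()


def test_path_small_d_keeps_entire_path():
    g = path_graph(8)
    s = teasar(g, (0, 0, 0), d=5.0)       # d < edge pitch 10
    assert s.n_vertices == 8
    assert s.is_tree()
    assert s.vertex_l2_ids[s.root_vertex] == 0
    degs = sorted(d for _, d in nx.Graph(s.edges).degree())
    assert degs == [1, 1] + [2] * 6


def test_path_large_d_collapses_interior():
    g = path_graph(8)
    s = teasar(g, (0, 0, 0), d=100.0)     # everything within d of first path
    assert s.is_tree()
    # the first traced path spans root..farthest, so endpoints survive
    assert 0 in s.vertex_l2_ids and 7 in s.vertex_l2_ids
    assert set(s.invalidation_map) == set(g.nodes)


def test_y_fixture_three_leaves_one_branch():
    g = y_graph(arm=5)
    s = teasar(g, (50.0, 0.0, 0.0), d=15.0)   # d < arm length 50
    assert s.is_tree()
    degrees = dict(nx.Graph(s.edges).degree())
    leaf_count = sum(1 for d in degrees.values() if d == 1)
    branch = [v for v, d in degrees.items() if d == 3]
    assert leaf_count == 3
    assert len(branch) == 1
    assert s.vertex_l2_ids[branch[0]] == 0    # the hub


def test_sub_d_spur_absorbed():
    """A spur shorter than d is invalidated, not traced as a branch."""
    coords = {i: (i * 10.0, 0.0, 0.0) for i in range(8)}
    coords[100] = (40.0, 10.0, 0.0)           # 1-edge spur off node 4
    edges = [(i, i + 1) for i in range(7)] + [(4, 100)]
    g = graph_from_coords(edges, coords)
    s = teasar(g, (0, 0, 0), d=25.0)
    assert 100 not in s.vertex_l2_ids         # absorbed
    assert s.invalidation_map[100] == s.vertex_l2_ids.index(4)
    degrees = dict(nx.Graph(s.edges).degree())
    assert all(d <= 2 for d in degrees.values())
    assert s.is_tree()


def test_invalidation_map_total_and_self_mapping():
    rng = np.random.default_rng(0)
    g = nx.random_labeled_tree(30, seed=3)
    coords = {n: tuple(rng.uniform(0, 100, 3)) for n in g.nodes}
    g = graph_from_coords(list(g.edges), coords)
    s = teasar(g, (0, 0, 0), d=30.0)
    assert set(s.invalidation_map) == set(g.nodes)
    for i, l2 in enumerate(s.vertex_l2_ids):
        assert s.invalidation_map[l2] == i
    assert s.is_tree()


def test_invalidated_within_d_of_mapped_vertex():
    rng = np.random.default_rng(1)
    g = nx.random_labeled_tree(25, seed=5)
    coords = {n: tuple(rng.uniform(0, 80, 3)) for n in g.nodes}
    g = graph_from_coords(list(g.edges), coords)
    d = 40.0
    s = teasar(g, (0, 0, 0), d=d)
    for l2, vertex in s.invalidation_map.items():
        target_l2 = s.vertex_l2_ids[vertex]
        dist = nx.shortest_path_length(g, l2, target_l2, weight="weight")
        assert dist <= d + 1e-9


def test_teasar_rejects_bad_input():
    g = path_graph(3)
    with pytest.raises(InvalidArgumentError):
        teasar(g, (0, 0, 0), d=-1.0)
    g.add_node(99, coord=np.zeros(3))
    with pytest.raises(InvalidArgumentError):
        teasar(g, (0, 0, 0), d=1.0)


def test_determinism():
    rng = np.random.default_rng(2)
    g = nx.random_labeled_tree(40, seed=9)
    coords = {n: tuple(rng.uniform(0, 100, 3)) for n in g.nodes}
    g = graph_from_coords(list(g.edges), coords)
    a = teasar(g, (0, 0, 0), d=25.0)
    b = teasar(g, (0, 0, 0), d=25.0)
    assert a.vertex_l2_ids == b.vertex_l2_ids
    assert a.edges == b.edges
    assert a.invalidation_map == b.invalidation_map


# ---------------------------------------------------------------------------
# On real volumes through the L2-graph
# ---------------------------------------------------------------------------

def test_tube_l2_graph_weights_and_centerline():
    vol, edges = tube_volume(k=6, chunk=8)
    g = mc.ChunkedGraph.from_volume(vol, edges, chunk_size=(8, 8, 8))
    cache = L2Cache(vol, g)
    cache.populate(0)
    root = g.roots_at(0)[0]
    wg = build_weighted_l2_graph(g, cache, root, 0)
    assert wg.number_of_nodes() == 6
    weights = [d["weight"] for _, _, d in wg.edges(data=True)]
    assert all(w > 0 for w in weights)
    assert np.allclose(weights, 8.0)     # chunk pitch in x
    s = teasar(wg, (0.0, 4.0, 4.0), d=4.0)
    assert s.is_tree() and s.n_vertices == 6
    # centerline: every vertex within one chunk diagonal of the tube axis
    diag = np.linalg.norm([8, 8, 8])
    for v in s.vertices:
        assert np.linalg.norm(v[1:] - np.array([3.5, 3.5])) <= diag


def test_attach_features_conserves_segment_totals(ws):
    rng = np.random.default_rng(4)
    random_edits(ws, 6, rng)
    t = ws.graph.clock.now
    root = max(ws.graph.roots_at(t),
               key=lambda r: len(ws.graph.get_leaves(r, t)))
    stats = ws.cache.segment_stats(root, t)
    rep = stats.per_l2.iloc[0]
    s = skeletonize_root(ws.graph, ws.cache, root, t,
                         (rep.rep_x, rep.rep_y, rep.rep_z))
    assert s.is_tree()
    feats = attach_features(s, ws.cache)
    assert sum(f["volume"] for f in feats.values()) \
        == pytest.approx(stats.volume)
    assert sum(f["voxel_count"] for f in feats.values()) == stats.voxel_count


def test_attach_annotations_via_invalidation(ws):
    t = ws.graph.clock.now
    root = max(ws.graph.roots_at(t),
               key=lambda r: len(ws.graph.get_leaves(r, t)))
    leaves = sorted(ws.graph.get_leaves(root, t))
    stats = ws.cache.segment_stats(root, t)
    rep = stats.per_l2.iloc[0]
    s = skeletonize_root(ws.graph, ws.cache, root, t,
                         (rep.rep_x, rep.rep_y, rep.rep_z))
    ann = [(f"syn{i}", sv) for i, sv in enumerate(leaves[:10])]
    outside = [sv for sv in ws.graph.label_of_sv_id
               if sv not in set(leaves)]
    if outside:
        ann.append(("other", outside[0]))
    per_vertex, unmapped = attach_annotations(s, ws.graph, ann, t)
    mapped = [k for keys in per_vertex.values() for k in keys]
    assert sorted(mapped) == sorted(f"syn{i}" for i in range(10))
    if outside:
        assert unmapped == ["other"]


def test_swc_output(tmp_path, ws):
    t = ws.graph.clock.now
    root = max(ws.graph.roots_at(t),
               key=lambda r: len(ws.graph.get_leaves(r, t)))
    rep = ws.cache.segment_stats(root, t).per_l2.iloc[0]
    s = skeletonize_root(ws.graph, ws.cache, root, t,
                         (rep.rep_x, rep.rep_y, rep.rep_z))
    path = tmp_path / "skel.swc"
    write_swc(s, path, cache=ws.cache)
    lines = [l.split() for l in path.read_text().splitlines()
             if not l.startswith("#")]
    assert len(lines) == s.n_vertices
    parents = [int(l[6]) for l in lines]
    assert parents.count(-1) == 1
    radii = [float(l[5]) for l in lines]
    assert all(r > 0 for r in radii)
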