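"""Hierarchy construction, root lookups, octree pruning, history."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import microcave as mc
from microcave.chunkedgraph import ChunkedGraph
from microcave.config import BitLayout
from microcave.errors import (InvalidArgumentError, NotFoundError,
                              StaleIDError)

from conftest import random_edits, oracle_vs_hierarchy_ok, tube_volume


try:
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(layer=st.integers(1, 255),
           chunk=st.tuples(st.integers(0, 4095), st.integers(0, 4095),
                           st.integers(0, 4095)),
           counter=st.integers(0, 2 ** 20 - 1))
    def test_node_id_packing_bijective(layer, chunk, counter):
        layout = BitLayout()
        packed = layout.pack(layer, chunk, counter)
        assert 0 <= packed < 2 ** 64
        assert layout.unpack(packed) == (layer, chunk, counter)
except ImportError:      # pragma: no cover - hypothesis is a test extra
    pass


def test_node_id_packing_roundtrip():
    layout = BitLayout()
    rng = np.random.default_rng(0)
    for _ in range(200):
        layer = int(rng.integers(1, 2 ** 8))
        chunk = tuple(int(v) for v in rng.integers(0, 2 ** 12, size=3))
        counter = int(rng.integers(0, 2 ** 20))
        packed = layout.pack(layer, chunk, counter)
        assert packed < 2 ** 64
        assert layout.unpack(packed) == (layer, chunk, counter)
        assert layout.layer_of(packed) == layer
    with pytest.raises(InvalidArgumentError):
        layout.pack(256, (0, 0, 0), 1)
    with pytest.raises(InvalidArgumentError):
        BitLayout(layer_bits=10)


def test_singleton_ingest_spine():
    vol = mc.LabelVolume(shape=(8, 8, 8), resolution=(1, 1, 1),
                         cell_labels=np.ones((8, 8, 8), np.int32),
                         supervoxel_labels=np.ones((8, 8, 8), np.int64))
    g = ChunkedGraph.from_volume(
        vol, pd.DataFrame(columns=["sv_a", "sv_b", "affinity"]),
        chunk_size=(8, 8, 8))
    roots = g.roots_at(0)
    assert len(roots) == 1
    # one node per layer up the spine
    sv = g.sv_id_of_label[1]
    assert g.get_root(sv, 0) == roots[0]
    assert len(g.nodes) == g.n_layers


def test_two_svs_one_edge_one_l2():
    sv = np.zeros((8, 8, 8), dtype=np.int64)
    sv[:4] = 1
    sv[4:] = 2
    vol = mc.LabelVolume(shape=(8, 8, 8), resolution=(1, 1, 1),
                         cell_labels=(sv > 0).astype(np.int32),
                         supervoxel_labels=sv)
    edges = pd.DataFrame([(1, 2, 0.9)], columns=["sv_a", "sv_b", "affinity"])
    g = ChunkedGraph.from_volume(vol, edges, chunk_size=(8, 8, 8))
    l2s = g.get_subgraph_layer(g.roots_at(0)[0], 2, 0)
    assert len(l2s) == 1
    assert set(g.nodes[l2s.pop()].children) == set(g.sv_id_of_label.values())


def test_ingest_rejects_unknown_supervoxel():
    vol = mc.LabelVolume(shape=(8, 8, 8), resolution=(1, 1, 1),
                         cell_labels=np.ones((8, 8, 8), np.int32),
                         supervoxel_labels=np.ones((8, 8, 8), np.int64))
    edges = pd.DataFrame([(1, 99, 0.9)], columns=["sv_a", "sv_b", "affinity"])
    with pytest.raises(InvalidArgumentError):
        ChunkedGraph.from_volume(vol, edges, chunk_size=(8, 8, 8))


def test_root_count_matches_union_find_oracle(ws):
    g = nx.Graph()
    g.add_nodes_from(ws.graph.label_of_sv_id)
    g.add_edges_from(ws.graph.effective_edges(0))
    assert len(ws.graph.roots_at(0)) == nx.number_connected_components(g)
    assert oracle_vs_hierarchy_ok(ws, 0)


def test_error_free_ingest_groups_cells(make_workspace):
    w = make_workspace(seed=3, error_rate=0.0)
    for lbl, cell in w.gt.sv_to_cell.items():
        sv = w.graph.sv_id_of_label[lbl]
        root = w.graph.get_root(sv, 0)
        peers = {w.gt.sv_to_cell[w.graph.label_of_sv_id[s]]
                 for s in w.graph.get_leaves(root, 0)}
        assert peers == {cell}


def test_get_root_errors(ws):
    with pytest.raises(NotFoundError):
        ws.graph.get_root(12345, 0)
    with pytest.raises(InvalidArgumentError):
        sv = next(iter(ws.graph.label_of_sv_id))
        ws.graph.get_root(sv, -1)


def test_get_leaves_bbox_equals_bruteforce(ws):
    rng = np.random.default_rng(0)
    root = max(ws.graph.roots_at(0),
               key=lambda r: len(ws.graph.get_leaves(r, 0)))
    all_leaves = ws.graph.get_leaves(root, 0)
    assert ws.graph.get_leaves(root, 0, bbox=((0, 0, 0), ws.vol.shape)) \
        == all_leaves
    far = ((1000, 1000, 1000), (1016, 1016, 1016))
    assert ws.graph.get_leaves(root, 0, bbox=far) == set()
    for _ in range(25):
        lo = rng.integers(0, 24, size=3)
        hi = lo + rng.integers(4, 16, size=3)
        bbox = (tuple(int(v) for v in lo), tuple(int(v) for v in hi))
        expected = set()
        for sv in all_leaves:
            node = ws.graph.nodes[sv]
            clo, chi = ws.graph.chunk_extent(node.chunk, 1)
            if all(a < bh and bl < b for a, b, bl, bh in
                   zip(clo, chi, *bbox)):
                expected.add(sv)
        assert ws.graph.get_leaves(root, 0, bbox=bbox) == expected


def test_subgraph_layer_consistency(ws):
    for root in ws.graph.roots_at(0):
        l2s = ws.graph.get_subgraph_layer(root, 2, 0)
        union = set()
        for l2 in l2s:
            union |= set(ws.graph.nodes[l2].children)
        assert union == ws.graph.get_leaves(root, 0)


def test_l2_graph_connected_and_tube_is_path():
    vol, edges = tube_volume(k=5, chunk=8)
    g = ChunkedGraph.from_volume(vol, edges, chunk_size=(8, 8, 8))
    root = g.roots_at(0)[0]
    lg = g.get_l2_graph(root, 0)
    assert lg.number_of_nodes() == 5
    degrees = sorted(d for _, d in lg.degree())
    assert degrees == [1, 1, 2, 2, 2]       # path graph
    assert nx.is_connected(lg)


def test_l2_graph_one_chunk_segment():
    vol, _ = tube_volume(k=1, chunk=8)
    g = ChunkedGraph.from_volume(
        vol, pd.DataFrame(columns=["sv_a", "sv_b", "affinity"]),
        chunk_size=(8, 8, 8))
    lg = g.get_l2_graph(g.roots_at(0)[0], 0)
    assert lg.number_of_nodes() == 1 and lg.number_of_edges() == 0


def test_chunk_extent_arithmetic_and_tiling(ws):
    g = ws.graph
    assert g.chunk_extent((0, 0, 0), 2) == ((0, 0, 0), (16, 16, 16))
    assert g.chunk_extent((0, 0, 0), 3) == ((0, 0, 0), (32, 32, 32))
    assert g.chunk_extent((1, 0, 2), 2) == ((16, 0, 32), (32, 16, 48))
    # extents at one layer tile without overlap
    boxes = [g.chunk_extent((x, y, z), 2)
             for x in range(2) for y in range(2) for z in range(2)]
    total = sum(np.prod(np.array(h) - np.array(l)) for l, h in boxes)
    assert total == 32 ** 3


def test_history_immutable_under_edits(ws):
    rng = np.random.default_rng(1)
    before = {t: ws.hierarchy_partition(t) for t in range(1)}
    parts_at = {}
    random_edits(ws, 10, rng)
    t_mid = ws.graph.clock.now
    for t in range(t_mid + 1):
        parts_at[t] = ws.hierarchy_partition(t)
    random_edits(ws, 10, rng)
    for t in range(t_mid + 1):
        assert ws.hierarchy_partition(t) == parts_at[t]
    assert ws.hierarchy_partition(0) == before[0]


def test_stale_root_raises_with_successors(ws):
    rng = np.random.default_rng(2)
    ops = random_edits(ws, 10, rng)
    assert ops, "no edits applied"
    op = ops[-1]
    old = op.old_roots[0]
    t_now = ws.graph.clock.now
    with pytest.raises(StaleIDError) as exc:
        ws.graph.get_leaves(old, t_now)
    assert set(exc.value.successors) <= set(ws.graph.roots_at(t_now))
    assert exc.value.successors


def test_save_load_roundtrip(tmp_path, ws):
    rng = np.random.default_rng(3)
    random_edits(ws, 8, rng)
    ws.graph.save(tmp_path / "g")
    back = ChunkedGraph.load(tmp_path / "g")
    t = ws.graph.clock.now
    assert back.clock.now == t
    for tt in range(t + 1):
        parts_a = ws.hierarchy_partition(tt)
        parts_b = {}
        for sv in back.label_of_sv_id:
            parts_b.setdefault(back.get_root(sv, tt), []).append(sv)
        assert parts_a == sorted(sorted(c) for c in parts_b.values())
    assert set(back.lineage.edges()) == set(ws.graph.lineage.edges())
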