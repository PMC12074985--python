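"""Edit semantics: fake edges, reactivation, expansion, min cut, lineage."""

import itertools

import networkx as nx
import numpy as np
import pytest

import microcave as mc
from microcave.edits import (build_local_graph, expand_split_labels, min_cut)
from microcave.errors import (AmbiguousSplitError, ConcurrentEditError,
                              InvalidSplitError, NoOpEditError,
                              NothingToCutError, NotFoundError)

from conftest import random_edits, oracle_vs_hierarchy_ok


def _graph_from_edges(weighted_edges):
    g = nx.Graph()
    for u, v, aff in weighted_edges:
        g.add_edge(u, v, affinity=aff, is_fake=False,
                   w=max(-np.log(min(aff, 1.0)), 0.0))
    return g


# ---------------------------------------------------------------------------
# min_cut
# ---------------------------------------------------------------------------

def test_min_cut_unique_weak_edge():
    g = _graph_from_edges([(1, 2, 0.9), (2, 3, 0.2)])
    assert min_cut(g, [1], [3]) == [(2, 3)]


def test_min_cut_already_disconnected():
    g = _graph_from_edges([(1, 2, 0.9)])
    g.add_node(3)
    with pytest.raises(NothingToCutError):
        min_cut(g, [1], [3])


def brute_force_min_cut_weight(g, sources, sinks):
    """Exhaustive bipartition oracle for small graphs."""
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    best = None
    for mask in range(1 << len(nodes)):
        if any(not (mask >> idx[s]) & 1 for s in sources):
            continue
        if any((mask >> idx[t]) & 1 for t in sinks):
            continue
        w = sum(d["affinity"] for u, v, d in g.edges(data=True)
                if ((mask >> idx[u]) & 1) != ((mask >> idx[v]) & 1))
        if best is None or w < best:
            best = w
    return best


def test_min_cut_matches_exhaustive_oracle():
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 60:
        n = int(rng.integers(4, 9))
        m = int(rng.integers(3, 13))
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2 ** 31)))
        if g.number_of_edges() == 0:
            continue
        for u, v in g.edges():
            g.edges[u, v].update(affinity=float(rng.uniform(0.05, 1.0)),
                                 is_fake=False, w=1.0)
        nodes = sorted(g.nodes)
        s, t = [nodes[0]], [nodes[-1]]
        if not nx.has_path(g, s[0], t[0]):
            continue
        cut = min_cut(g, s, t)
        w = sum(g.edges[e]["affinity"] for e in cut)
        assert w == pytest.approx(brute_force_min_cut_weight(g, s, t))
        # cut actually disconnects
        h = g.copy()
        h.remove_edges_from(cut)
        assert not nx.has_path(h, s[0], t[0])
        checked += 1


def test_min_cut_deterministic():
    g = _graph_from_edges([(1, 2, 0.5), (2, 3, 0.5), (1, 4, 0.5), (4, 3, 0.5)])
    cuts = {tuple(min_cut(g, [1], [3])) for _ in range(5)}
    assert len(cuts) == 1


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------

def test_expand_connected_side_unchanged():
    g = _graph_from_edges([(1, 2, 0.9), (2, 3, 0.9), (3, 4, 0.9)])
    src, snk = expand_split_labels([1, 2], [4], g)
    assert src == {1, 2} and snk == {4}


def test_expand_adds_intermediate_supervoxel():
    g = _graph_from_edges([(1, 2, 0.9), (2, 3, 0.9), (3, 4, 0.2)])
    src, snk = expand_split_labels([1, 3], [4], g)
    assert src == {1, 2, 3}


def test_expand_prefers_high_affinity_corridor():
    # two routes 1->4: via 2 (strong) or via 5 (weak); path metric -log aff
    g = _graph_from_edges([(1, 2, 0.9), (2, 4, 0.9), (1, 5, 0.1), (5, 4, 0.1)])
    src, _ = expand_split_labels([1, 4], [6], _with_extra(g))
    assert src == {1, 2, 4}


def _with_extra(g):
    g = g.copy()
    g.add_edge(4, 6, affinity=0.9, is_fake=False, w=0.1)
    return g


def test_expand_overlap_is_ambiguous():
    g = _graph_from_edges([(1, 2, 0.9), (2, 3, 0.9)])
    with pytest.raises(AmbiguousSplitError):
        expand_split_labels([1, 3], [2], g)


def test_expand_sides_connected_on_random_graphs():
    rng = np.random.default_rng(7)
    for _ in range(20):
        g = nx.connected_watts_strogatz_graph(
            12, 4, 0.3, seed=int(rng.integers(2 ** 31)))
        for u, v in g.edges():
            g.edges[u, v].update(affinity=float(rng.uniform(0.1, 1.0)),
                                 is_fake=False)
            g.edges[u, v]["w"] = -np.log(g.edges[u, v]["affinity"])
        nodes = sorted(g.nodes)
        picks = [int(v) for v in rng.choice(nodes, size=4, replace=False)]
        try:
            src, snk = expand_split_labels(picks[:2], picks[2:], g)
        except AmbiguousSplitError:
            continue
        assert nx.is_connected(g.subgraph(src))
        assert nx.is_connected(g.subgraph(snk))
        assert not (src & snk)


# ---------------------------------------------------------------------------
# merge / split through the engine
# ---------------------------------------------------------------------------

def test_merge_creates_fake_edge_and_split_undoes_it(make_workspace):
    ws = make_workspace(seed=0, error_rate=0.0)
    g = ws.graph
    t0 = g.clock.now
    by_root = {}
    for sv in sorted(g.label_of_sv_id):
        by_root.setdefault(g.get_root(sv, t0), []).append(sv)
    roots = sorted(by_root)
    assert len(roots) >= 2, "fixture needs >= 2 components"
    a, b = by_root[roots[0]][0], by_root[roots[1]][0]
    before = ws.hierarchy_partition(t0)

    op = ws.editor.merge(a, b)
    assert op.kind == "merge" and not op.edges_removed
    assert len(op.new_roots) == 1
    assert set(op.old_roots) == {roots[0], roots[1]}
    new_root = op.new_roots[0]
    assert g.get_root(a, op.t) == g.get_root(b, op.t) == new_root
    # supervoxel conservation through the merge
    leaves_new = g.get_leaves(new_root, op.t)
    assert leaves_new == set(by_root[roots[0]]) | set(by_root[roots[1]])

    op2 = ws.editor.split([a], [b])
    assert op2.kind == "split" and not op2.edges_added
    assert op2.edges_removed == [tuple(sorted((a, b)))]
    assert ws.hierarchy_partition(g.clock.now) == before


def test_merge_same_root_is_noop_error(ws):
    g = ws.graph
    root = g.roots_at(0)[0]
    leaves = sorted(g.get_leaves(root, 0))
    if len(leaves) < 2:
        pytest.skip("singleton root")
    with pytest.raises(NoOpEditError):
        ws.editor.merge(leaves[0], leaves[1])


def test_merge_reactivates_removed_edges(ws):
    """A merge undoing a split re-activates the stored edges (no fake edge)."""
    g = ws.graph
    rng = np.random.default_rng(0)
    ops = random_edits(ws, 15, rng)
    split_op = next((o for o in ops if o.kind == "split" and o.edges_removed),
                    None)
    assert split_op is not None
    a, b = split_op.edges_removed[0]
    t = g.clock.now
    if g.get_root(a, t) == g.get_root(b, t):
        pytest.skip("split did not separate locally")
    merge_op = ws.editor.merge(a, b)
    added_keys = {tuple(sorted(e[:2])) for e in merge_op.edges_added}
    assert tuple(sorted((a, b))) in added_keys
    assert all(not g.edges[k].is_fake for k in added_keys)


def test_split_requires_single_root(make_workspace):
    ws = make_workspace(seed=0, error_rate=0.0)
    g = ws.graph
    roots = g.roots_at(0)
    if len(roots) < 2:
        pytest.skip("need two roots")
    a = sorted(g.get_leaves(roots[0], 0))[0]
    b = sorted(g.get_leaves(roots[1], 0))[0]
    with pytest.raises(InvalidSplitError):
        ws.editor.split([a], [b])


def test_split_cuts_injected_bridge(make_workspace):
    """Dumbbell: the low-affinity injected edge is what the cut removes."""
    w = make_workspace(seed=11, error_rate=0.15)
    merges = [e for e in w.gt.injected_errors if e.kind == "merge"]
    assert merges
    did = 0
    for err in merges[:5]:
        a = w.graph.sv_id_of_label[err.sv_a]
        b = w.graph.sv_id_of_label[err.sv_b]
        t = w.graph.clock.now
        if w.graph.get_root(a, t) != w.graph.get_root(b, t):
            continue
        op = w.editor.split([a], [b])
        for u, v in op.edges_removed:
            la = w.graph.label_of_sv_id[u]
            lb = w.graph.label_of_sv_id[v]
            assert w.gt.sv_to_cell[la] != w.gt.sv_to_cell[lb]
        did += 1
    assert did > 0


def test_multimerge_equals_sequential_any_order(make_workspace):
    base_roots = None
    partitions = []
    for perm_seed in range(3):
        w = make_workspace(seed=21, error_rate=0.0)
        g = w.graph
        by_root = {}
        for sv in sorted(g.label_of_sv_id):
            by_root.setdefault(g.get_root(sv, 0), []).append(sv)
        groups = [v for _, v in sorted(by_root.items())][:4]
        if len(groups) < 3:
            pytest.skip("need >= 3 components")
        pairs = [(groups[i][0], groups[i + 1][0])
                 for i in range(len(groups) - 1)]
        pairs.append((groups[0][0], groups[-1][0]))    # redundant pair
        rng = np.random.default_rng(perm_seed)
        order = list(rng.permutation(len(pairs)))
        if perm_seed == 0:
            op = w.editor.multimerge([pairs[i] for i in order])
            assert op.kind == "multimerge"
        else:
            for i in order:
                a, b = pairs[i]
                t = g.clock.now
                try:
                    w.editor.merge(a, b)
                except NoOpEditError:
                    pass
        partitions.append(w.hierarchy_partition(g.clock.now))
    assert partitions[0] == partitions[1] == partitions[2]


def test_multimerge_all_same_root_noop(ws):
    g = ws.graph
    root = g.roots_at(0)[0]
    leaves = sorted(g.get_leaves(root, 0))
    if len(leaves) < 2:
        pytest.skip("singleton root")
    with pytest.raises(NoOpEditError):
        ws.editor.multimerge([(leaves[0], leaves[1])])


def test_chain_multimerge_single_root(make_workspace):
    w = make_workspace(seed=21, error_rate=0.0)
    g = w.graph
    by_root = {}
    for sv in sorted(g.label_of_sv_id):
        by_root.setdefault(g.get_root(sv, 0), []).append(sv)
    groups = [v for _, v in sorted(by_root.items())][:3]
    if len(groups) < 3:
        pytest.skip("need >= 3 components")
    op = w.editor.multimerge([(groups[0][0], groups[1][0]),
                              (groups[1][0], groups[2][0])])
    assert len(op.new_roots) == 1


# ---------------------------------------------------------------------------
# rebuild locality, atomicity, lineage
# ---------------------------------------------------------------------------

def test_edit_locality_untouched_chunks_keep_ids(ws):
    rng = np.random.default_rng(4)
    g = ws.graph
    before = {nid for nid, n in g.nodes.items() if n.layer == 2}
    ops = random_edits(ws, 5, rng)
    assert ops
    for op in ops:
        touched_chunks = set()
        for a, b, _ in op.edges_added:
            touched_chunks.update((g.nodes[a].chunk, g.nodes[b].chunk))
        for a, b in op.edges_removed:
            touched_chunks.update((g.nodes[a].chunk, g.nodes[b].chunk))
        for l2 in op.new_l2_ids:
            assert g.nodes[l2].chunk in touched_chunks
    # all pre-existing L2 nodes still exist as records (IDs never reused)
    assert before <= {nid for nid, n in g.nodes.items() if n.layer == 2}


def test_failed_edit_leaves_no_trace(ws):
    g = ws.graph
    t0 = g.clock.now
    n_nodes = len(g.nodes)
    n_ops = len(g.operations)
    root = g.roots_at(t0)[0]
    leaves = sorted(g.get_leaves(root, t0))
    with pytest.raises(NoOpEditError):
        ws.editor.merge(leaves[0], leaves[1])
    assert g.clock.now == t0
    assert len(g.nodes) == n_nodes
    assert len(g.operations) == n_ops


def test_edit_lock_serializes(ws):
    ws.graph.acquire_edit_lock()
    with pytest.raises(ConcurrentEditError):
        ws.editor.merge((0, 0, 0), (1, 1, 1))
    ws.graph.release_edit_lock()


def test_lineage_split_then_merge_mapping(ws):
    rng = np.random.default_rng(5)
    g = ws.graph
    ops = random_edits(ws, 12, rng)
    split_op = next((o for o in ops if o.kind == "split"
                     and len(o.new_roots) == 2), None)
    if split_op is None:
        pytest.skip("no separating split occurred")
    old = split_op.old_roots[0]
    r1, r2 = split_op.new_roots
    assert g.map_roots([r1], split_op.t, split_op.t - 1) == {old}
    forward = g.map_roots([old], split_op.t - 1, split_op.t)
    assert {r1, r2} <= forward


def test_map_roots_identity_without_edits(ws):
    roots = ws.graph.roots_at(0)
    for r in roots[:5]:
        assert ws.graph.map_roots([r], 0, 0) == {r}
    with pytest.raises(NotFoundError):
        ws.graph.map_roots([123], 0, 0)


def test_map_roots_agrees_with_leaf_recomputation(ws):
    rng = np.random.default_rng(6)
    g = ws.graph
    random_edits(ws, 15, rng)
    t_hi = g.clock.now
    for t_lo in (0, t_hi // 2):
        for root in g.roots_at(t_lo):
            mapped = g.map_roots([root], t_lo, t_hi)
            exact = {g.get_root(sv, t_hi)
                     for sv in g.get_leaves(root, t_lo)}
            assert exact <= mapped       # overinclusive, never missing
            assert exact                 # and non-empty


def test_partition_invariant_after_each_edit(ws):
    rng = np.random.default_rng(8)
    random_edits(ws, 15, rng)
    for t in range(ws.graph.clock.now + 1):
        assert oracle_vs_hierarchy_ok(ws, t)
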