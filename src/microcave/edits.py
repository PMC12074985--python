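"""Proofreading edits: merge, multimerge, and min-cut splits.

Edits follow the interactive-proofreading semantics used on large EM
reconstructions:

* A **merge** first checks for OFF edges between the two components inside a
  local bounding box (the chunks of the selected supervoxels padded by one
  layer-2 chunk). If any exist they are all reactivated — a merge that
  undoes a prior split restores the stored edges. Otherwise a single *fake
  edge* is inserted between the two selected supervoxels, with a large
  affinity so user-asserted connections are cut last.
* A **split** takes source and sink label sets, expands each side along
  affinity-weighted shortest paths so it is connected, and removes the
  canonical minimum cut (source-side residual reachability of the max
  flow). Splits act only on the local graph, so a cut can legitimately
  leave one root when the component stays connected outside the box.

Every edit is atomic, consumes one logical timestamp, rebuilds only the
affected chunks, and appends old-root -> new-root edges to the lineage
graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import networkx as nx

from .chunkedgraph import ChunkedGraph, edge_key
from .config import get_logger
from .errors import (AmbiguousSplitError, CutImpossibleError,
                     InvalidArgumentError, InvalidSplitError, NoOpEditError,
                     NothingToCutError, NotFoundError)
from .synthetic import LabelVolume

logger = get_logger("microcave.edits")

DEFAULT_FAKE_AFFINITY = 1.0e6
_UNCUTTABLE = 1.0e15


@dataclass
class EditOperation:
    op_id: int
    kind: Literal["merge", "split", "multimerge"]
    t: int
    user_points: list = field(default_factory=list)
    sources: tuple[int, ...] = ()
    sinks: tuple[int, ...] = ()
    edges_added: list[tuple[int, int, float]] = field(default_factory=list)
    edges_removed: list[tuple[int, int]] = field(default_factory=list)
    old_roots: tuple[int, ...] = ()
    new_roots: tuple[int, ...] = ()
    new_l2_ids: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# Local graph extraction
# ---------------------------------------------------------------------------

def _pad_chunks(graph: ChunkedGraph, svs: Iterable[int]) -> set[tuple]:
    """Chunks of the given supervoxels padded by one chunk per direction."""
    out: set[tuple] = set()
    for sv in svs:
        cx, cy, cz = graph.nodes[sv].chunk
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    c = (cx + dx, cy + dy, cz + dz)
                    if all(v >= 0 for v in c) and c in graph.chunk_svs:
                        out.add(c)
    return out


def _local_svs(graph: ChunkedGraph, chunks: set[tuple]) -> set[int]:
    out: set[int] = set()
    for c in chunks:
        out.update(graph.chunk_svs.get(c, ()))
    return out


def build_local_graph(graph: ChunkedGraph, svs: set[int], t: int) -> nx.Graph:
    """Effective supervoxel graph at time t restricted to ``svs``.

    Edge attributes: ``affinity`` (fake edges keep their large value),
    ``is_fake`` and ``w`` = max(-log(min(affinity, 1)), 0), the path metric
    that prefers high-affinity corridors.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(svs))
    for sv in sorted(svs):
        for key in sorted(graph.sv_edges.get(sv, ())):
            a, b = key
            if a in svs and b in svs and graph.edges[key].state_at(t):
                rec = graph.edges[key]
                g.add_edge(a, b, affinity=rec.affinity, is_fake=rec.is_fake,
                           w=max(-math.log(min(rec.affinity, 1.0)), 0.0))
    return g


# ---------------------------------------------------------------------------
# Split primitives
# ---------------------------------------------------------------------------

def expand_split_labels(sources: Sequence[int], sinks: Sequence[int],
                        local_graph: nx.Graph
                        ) -> tuple[frozenset, frozenset]:
    """Connect each label set along affinity-weighted shortest paths.

    Every supervoxel on a shortest path (weight ``-log affinity``) between a
    pair of same-side labels joins that side. Sides must stay disjoint.
    """
    sources, sinks = list(sources), list(sinks)
    if not sources or not sinks:
        raise InvalidArgumentError("sources and sinks must be non-empty")
    expanded = []
    for side in (sources, sinks):
        side = sorted(set(side))
        for sv in side:
            if sv not in local_graph:
                raise NotFoundError(f"label {sv} not in the local graph")
        out = set(side)
        anchor = side[0]
        for other in side[1:]:
            try:
                path = nx.shortest_path(local_graph, anchor, other, weight="w")
            except nx.NetworkXNoPath:
                raise InvalidSplitError(
                    f"labels {anchor} and {other} are not connected in the "
                    "local graph; enlarge or move the labels")
            out.update(path)
        expanded.append(frozenset(out))
    src, snk = expanded
    if src & snk:
        raise AmbiguousSplitError(
            f"expanded source and sink sets overlap on {sorted(src & snk)}; "
            "refine the labels")
    return src, snk


def min_cut(local_graph: nx.Graph, sources: Iterable[int],
            sinks: Iterable[int]) -> list[tuple[int, int]]:
    """Minimum-total-affinity edge set disconnecting sources from sinks.

    Capacity = affinity (fake edges carry their large constant). The
    returned cut is the canonical source-side cut of the max-flow residual
    reachability, which fixes tie-breaking.
    """
    sources, sinks = sorted(set(sources)), sorted(set(sinks))
    d = nx.DiGraph()
    for u, v, data in sorted(local_graph.edges(data=True)):
        d.add_edge(u, v, capacity=data["affinity"])
        d.add_edge(v, u, capacity=data["affinity"])
    SRC, SNK = "__source__", "__sink__"
    for s in sources:
        d.add_edge(SRC, s, capacity=_UNCUTTABLE)
    for s in sinks:
        d.add_edge(s, SNK, capacity=_UNCUTTABLE)
    if not nx.has_path(d, SRC, SNK):
        raise NothingToCutError("sources and sinks are already disconnected")
    # Compute a true max flow, then take source-side residual reachability
    # with a tolerance: networkx's own minimum_cut partition relies on exact
    # flow == capacity comparisons and breaks down on float capacities.
    residual = nx.algorithms.flow.edmonds_karp(d, SRC, SNK)
    value = residual.graph["flow_value"]
    if value == 0:
        raise NothingToCutError("sources and sinks are already disconnected")
    if value >= _UNCUTTABLE:
        raise CutImpossibleError("all source-sink paths are uncuttable")
    tol = 1e-9 * max(value, 1.0)
    part_s = {SRC}
    stack = [SRC]
    while stack:
        u = stack.pop()
        for v, data in residual[u].items():
            if v not in part_s and data["capacity"] - data["flow"] > tol:
                part_s.add(v)
                stack.append(v)
    cut = []
    for u, v in local_graph.edges():
        if (u in part_s) != (v in part_s):
            cut.append(edge_key(u, v))
    return sorted(cut)


# ---------------------------------------------------------------------------
# Edit engine
# ---------------------------------------------------------------------------

class EditEngine:
    """Applies serialized edits to a :class:`ChunkedGraph`.

    ``vol`` is optional and only needed to resolve voxel-coordinate points
    to supervoxels; all operations also accept supervoxel IDs directly.
    ``post_edit_hook(op)`` runs synchronously after each edit (the desk-scale
    stand-in for an event queue) — the morphology cache subscribes here.
    """

    def __init__(self, graph: ChunkedGraph, vol: Optional[LabelVolume] = None,
                 fake_edge_affinity: float = DEFAULT_FAKE_AFFINITY):
        self.graph = graph
        self.vol = vol
        self.fake_edge_affinity = float(fake_edge_affinity)
        self.post_edit_hooks: list = []
        self._next_op_id = 1

    # -- point handling -----------------------------------------------------

    def resolve_point(self, point) -> int:
        if self.vol is None:
            raise InvalidArgumentError("no volume attached; pass supervoxel IDs")
        label = self.vol.sv_at(point)
        if label == 0:
            raise NotFoundError(f"point {tuple(point)} is on background")
        return self.graph.sv_id_of_label[label]

    def _as_sv(self, point_or_sv) -> int:
        if isinstance(point_or_sv, (tuple, list)):
            return self.resolve_point(point_or_sv)
        sv = int(point_or_sv)
        if sv not in self.graph.nodes or self.graph.nodes[sv].layer != 1:
            raise NotFoundError(f"unknown supervoxel {sv}")
        return sv

    # -- merge --------------------------------------------------------------

    def _merge_edges_for_pair(self, sv_a: int, sv_b: int, t_prev: int,
                              root_a: int, root_b: int):
        """Edges a single merge would activate: reactivations or one fake."""
        graph = self.graph
        chunks = _pad_chunks(graph, [sv_a, sv_b])
        local = _local_svs(graph, chunks)
        comp_a = {sv for sv in local if graph.get_root(sv, t_prev) == root_a}
        comp_b = {sv for sv in local if graph.get_root(sv, t_prev) == root_b}
        off = []
        for sv in sorted(comp_a):
            for key in sorted(graph.sv_edges.get(sv, ())):
                other = key[0] if key[1] == sv else key[1]
                if other in comp_b and not graph.edges[key].state_at(t_prev):
                    off.append(key)
        if off:
            return [(k[0], k[1], graph.edges[k].affinity,
                     graph.edges[k].is_fake) for k in sorted(set(off))]
        return [(sv_a, sv_b, self.fake_edge_affinity, True)]

    def merge(self, point_a, point_b) -> EditOperation:
        """Merge the segments under two points (or supervoxel IDs)."""
        graph = self.graph
        graph.acquire_edit_lock()
        try:
            sv_a, sv_b = self._as_sv(point_a), self._as_sv(point_b)
            t_prev = graph.clock.now
            root_a = graph.get_root(sv_a, t_prev)
            root_b = graph.get_root(sv_b, t_prev)
            if root_a == root_b:
                raise NoOpEditError(
                    f"supervoxels already share root {root_a}")
            added = self._merge_edges_for_pair(sv_a, sv_b, t_prev,
                                               root_a, root_b)
            t = graph.clock.tick()
            result = graph.apply_edge_changes(added, [], t)
            return self._finish("merge", t, [point_a, point_b],
                                added=added, removed=[], result=result,
                                t_prev=t_prev)
        finally:
            graph.release_edit_lock()

    def multimerge(self, pairs) -> EditOperation:
        """Apply several merges as one atomic operation at one timestamp.

        The resulting partition equals sequential merges in any order;
        pairs whose endpoints are already connected (directly or through
        earlier pairs) are filtered out.
        """
        graph = self.graph
        if not pairs:
            raise InvalidArgumentError("multimerge needs at least one pair")
        graph.acquire_edit_lock()
        try:
            t_prev = graph.clock.now
            sv_pairs = [(self._as_sv(a), self._as_sv(b)) for a, b in pairs]
            root_of = {sv: graph.get_root(sv, t_prev)
                       for pair in sv_pairs for sv in pair}
            uf_parent = {r: r for r in root_of.values()}

            def find(x):
                while uf_parent[x] != x:
                    uf_parent[x] = uf_parent[uf_parent[x]]
                    x = uf_parent[x]
                return x

            added = []
            for sv_a, sv_b in sv_pairs:
                ra, rb = find(root_of[sv_a]), find(root_of[sv_b])
                if ra == rb:
                    continue
                added.extend(self._merge_edges_for_pair(
                    sv_a, sv_b, t_prev, root_of[sv_a], root_of[sv_b]))
                uf_parent[rb] = ra
            if not added:
                raise NoOpEditError("all pairs already share a root")
            t = graph.clock.tick()
            result = graph.apply_edge_changes(sorted(set(added)), [], t)
            return self._finish("multimerge", t, list(pairs), added=added,
                                removed=[], result=result, t_prev=t_prev)
        finally:
            graph.release_edit_lock()

    # -- split --------------------------------------------------------------

    def _resolve_split(self, source_points, sink_points):
        """Resolve points, extract the local graph, expand and cut."""
        graph = self.graph
        sources = [self._as_sv(p) for p in source_points]
        sinks = [self._as_sv(p) for p in sink_points]
        t_prev = graph.clock.now
        roots = {graph.get_root(sv, t_prev) for sv in sources + sinks}
        if len(roots) != 1:
            raise InvalidSplitError(
                f"labels resolve to {len(roots)} roots; a split acts on one")
        root = roots.pop()
        chunks = _pad_chunks(graph, sources + sinks)
        local = {sv for sv in _local_svs(graph, chunks)
                 if graph.get_root(sv, t_prev) == root}
        local_graph = build_local_graph(graph, local, t_prev)
        src, snk = expand_split_labels(sources, sinks, local_graph)
        return min_cut(local_graph, src, snk), src, snk, t_prev

    def preview_split(self, source_points, sink_points
                      ) -> list[tuple[int, int]]:
        """The edges a split would remove, without applying anything."""
        cut, _, _, _ = self._resolve_split(source_points, sink_points)
        return cut

    def split(self, source_points, sink_points) -> EditOperation:
        """Split one segment by a min cut between expanded label sets."""
        graph = self.graph
        graph.acquire_edit_lock()
        try:
            cut, src, snk, t_prev = self._resolve_split(source_points,
                                                        sink_points)
            t = graph.clock.tick()
            result = graph.apply_edge_changes([], cut, t)
            op = self._finish("split", t,
                              [list(source_points), list(sink_points)],
                              added=[], removed=cut, result=result,
                              t_prev=t_prev)
            op.sources, op.sinks = tuple(sorted(src)), tuple(sorted(snk))
            return op
        finally:
            graph.release_edit_lock()

    # -- shared tail --------------------------------------------------------

    def _finish(self, kind, t, user_points, added, removed, result, t_prev
                ) -> EditOperation:
        graph = self.graph
        op = EditOperation(
            op_id=self._next_op_id, kind=kind, t=t, user_points=user_points,
            edges_added=[(a, b, aff) for a, b, aff, _ in added],
            edges_removed=list(removed),
            old_roots=tuple(sorted(result.expired_roots)),
            new_roots=tuple(sorted(result.new_roots)),
            new_l2_ids=tuple(sorted(result.new_l2_ids)))
        self._next_op_id += 1
        new_leaves = {r: graph.get_leaves(r, t) for r in result.new_roots}
        for old in result.expired_roots:
            old_leaves = graph.get_leaves(old, t_prev)
            for new, leaves in new_leaves.items():
                if old_leaves & leaves:
                    graph.lineage.add_edge(old, new, op_id=op.op_id, t=t)
        graph.operations.append(op)
        logger.info("%s applied", kind,
                    extra={"op_id": op.op_id, "t": t})
        for hook in self.post_edit_hooks:
            hook(op)
        return op


# ---------------------------------------------------------------------------
# Lineage conveniences (thin wrappers over the graph's lineage store)
# ---------------------------------------------------------------------------

def map_roots(graph: ChunkedGraph, roots, t_from: int, t_to: int) -> set[int]:
    return graph.map_roots(roots, t_from, t_to)


def lineage(graph: ChunkedGraph, root: int, t_from: int, t_to: int):
    return graph.lineage_slice(root, t_from, t_to)
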