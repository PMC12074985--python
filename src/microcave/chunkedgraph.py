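"""Versioned, spatially chunked hierarchical supervoxel graph.

The volume is tiled into layer-2 chunks; each supervoxel is assigned to the
chunk holding its representative voxel (lexicographic-minimum foreground
voxel). Layer-2 nodes are the connected components of the effective edge
set restricted to one chunk; each higher layer groups ``fanout``^3 child
chunks and unions children linked by cross-chunk edges that become internal
at that layer, up to a top layer with a single chunk whose nodes are the
roots (one per global connected component — one putative cell).

Versioning model: the *edge log* is ground truth. Every edge carries a list
of timestamped ON/OFF events (ingest edges start ON at t=0; edits append
events), and the hierarchy is a derived index — every node has a validity
interval ``[created, expired)`` and a history of parent pointers, so any
query can be answered at any past timestamp. Edits rebuild only the chunks
touching affected edges; untouched siblings keep their IDs.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .config import INFINITY_T, BitLayout, LogicalClock
from .errors import (ConcurrentEditError, InvalidArgumentError, NotFoundError,
                     StaleIDError)
from .synthetic import LabelVolume, save_edges_binary


# ---------------------------------------------------------------------------
# Node and edge records
# ---------------------------------------------------------------------------

@dataclass
class Node:
    """One hierarchy node: a connected component within its chunk."""

    id: int
    layer: int
    chunk: tuple[int, int, int]
    children: tuple[int, ...]
    created: int
    expired: int = INFINITY_T
    # (t, parent_id) entries, ascending in t; parent at time t is the last
    # entry with entry_t <= t
    parents: list[tuple[int, int]] = field(default_factory=list)
    # divergence layer -> frozenset of cross-chunk supervoxel edge keys that
    # were effective when this node was minted (constant over its validity)
    cross_edges: dict[int, frozenset] = field(default_factory=dict)

    def valid_at(self, t: int) -> bool:
        return self.created <= t < self.expired


@dataclass
class EdgeRecord:
    affinity: float
    is_fake: bool = False
    # timestamped ON/OFF events, ascending in t
    events: list[tuple[int, bool]] = field(default_factory=list)

    def state_at(self, t: int) -> bool:
        state = False
        for et, on in self.events:
            if et > t:
                break
            state = on
        return state


@dataclass
class RebuildResult:
    t: int
    new_l2_ids: list[int]
    new_roots: list[int]
    expired_roots: list[int]


class _UnionFind:
    def __init__(self, items: Iterable):
        self.parent = {x: x for x in items}

    def find(self, x):
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def components(self) -> list[frozenset]:
        groups: dict = {}
        for x in self.parent:
            groups.setdefault(self.find(x), []).append(x)
        return [frozenset(v) for v in groups.values()]


def edge_key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# ChunkedGraph
# ---------------------------------------------------------------------------

class ChunkedGraph:
    def __init__(self, chunk_size=(16, 16, 16), fanout: int = 2,
                 layout: Optional[BitLayout] = None,
                 volume_shape: tuple[int, int, int] = (64, 64, 64),
                 clock: Optional[LogicalClock] = None):
        self.chunk_size = tuple(int(c) for c in chunk_size)
        self.fanout = int(fanout)
        self.layout = layout or BitLayout()
        self.volume_shape = tuple(int(s) for s in volume_shape)
        self.clock = clock or LogicalClock()

        grid = [max(1, -(-s // c)) for s, c in
                zip(self.volume_shape, self.chunk_size)]
        levels = 0
        while any(g > 1 for g in grid):
            grid = [-(-g // self.fanout) for g in grid]
            levels += 1
        self.n_layers = 2 + max(1, levels)

        self.nodes: dict[int, Node] = {}
        self.edges: dict[tuple[int, int], EdgeRecord] = {}
        self.sv_edges: dict[int, set] = {}          # sv id -> set of edge keys
        self.sv_id_of_label: dict[int, int] = {}
        self.label_of_sv_id: dict[int, int] = {}
        self.chunk_svs: dict[tuple, list[int]] = {}  # L2 chunk -> sv ids
        self._chunk_index: dict[tuple, list[int]] = {}  # (layer, chunk) -> node ids
        self._counters: dict[tuple, int] = {}
        self.lineage = nx.DiGraph()                 # root id -> successor root id
        self.operations: list = []                  # populated by the edit engine
        self._edit_lock = False

    # -- chunk arithmetic ---------------------------------------------------

    def chunk_of_voxel(self, voxel) -> tuple[int, int, int]:
        return tuple(int(v) // c for v, c in zip(voxel, self.chunk_size))

    def chunk_at_layer(self, l2_chunk, layer: int) -> tuple[int, int, int]:
        """Coordinate of the layer-``layer`` chunk containing an L2 chunk."""
        if layer <= 2:
            return tuple(l2_chunk)
        f = self.fanout ** (layer - 2)
        return tuple(c // f for c in l2_chunk)

    def chunk_extent(self, chunk, layer: int) -> tuple[tuple, tuple]:
        """Half-open voxel box ``[lo, hi)`` of a chunk (layer 1 == layer 2)."""
        f = self.fanout ** (max(layer, 2) - 2)
        lo = tuple(int(c) * s * f for c, s in zip(chunk, self.chunk_size))
        hi = tuple(l + s * f for l, s in zip(lo, self.chunk_size))
        return lo, hi

    def divergence_layer(self, chunk_a, chunk_b) -> int:
        """Smallest layer at which two L2 chunks share a chunk."""
        for layer in range(2, self.n_layers + 1):
            if self.chunk_at_layer(chunk_a, layer) == \
                    self.chunk_at_layer(chunk_b, layer):
                return layer
        return self.n_layers

    def _mint(self, layer: int, chunk) -> int:
        key = (layer, tuple(chunk))
        counter = self._counters.get(key, 0) + 1
        self._counters[key] = counter
        return self.layout.pack(layer, tuple(chunk), counter)

    # -- ingest -------------------------------------------------------------

    @classmethod
    def from_volume(cls, vol: LabelVolume, edges: pd.DataFrame,
                    chunk_size=(16, 16, 16), fanout: int = 2,
                    layout: Optional[BitLayout] = None,
                    clock: Optional[LogicalClock] = None) -> "ChunkedGraph":
        """Ingest a supervoxel volume plus its affinity edge list."""
        labels = vol.supervoxel_labels
        if labels is None:
            raise InvalidArgumentError("volume has no supervoxel labels")
        flat = labels.ravel()
        fg = flat > 0
        uniq, first = np.unique(flat[fg], return_index=True)
        flat_idx = np.flatnonzero(fg)[first]
        rep = np.stack(np.unravel_index(flat_idx, labels.shape), axis=1)
        rep_coords = {int(s): tuple(int(c) for c in rc)
                      for s, rc in zip(uniq, rep)}
        graph = cls(chunk_size=chunk_size, fanout=fanout, layout=layout,
                    volume_shape=vol.shape, clock=clock)
        graph.ingest(rep_coords, edges)
        return graph

    def ingest(self, rep_coords: dict[int, tuple], edges: pd.DataFrame) -> None:
        """Build the full hierarchy at t=0.

        ``rep_coords`` maps supervoxel label -> representative voxel, which
        fixes the chunk assignment; ``edges`` has columns sv_a/sv_b/affinity
        referencing those labels.
        """
        if self.nodes:
            raise InvalidArgumentError("graph already ingested")
        for label in sorted(rep_coords):
            chunk = self.chunk_of_voxel(rep_coords[label])
            sv_id = self._mint(1, chunk)
            self.sv_id_of_label[label] = sv_id
            self.label_of_sv_id[sv_id] = label
            self.chunk_svs.setdefault(chunk, []).append(sv_id)
            node = Node(id=sv_id, layer=1, chunk=chunk, children=(), created=0)
            self.nodes[sv_id] = node
            self._chunk_index.setdefault((1, chunk), []).append(sv_id)

        for row in edges.itertuples(index=False):
            a, b = int(row.sv_a), int(row.sv_b)
            if a not in self.sv_id_of_label or b not in self.sv_id_of_label:
                raise InvalidArgumentError(
                    f"edge ({a},{b}) references unknown supervoxel")
            key = edge_key(self.sv_id_of_label[a], self.sv_id_of_label[b])
            self.edges[key] = EdgeRecord(affinity=float(row.affinity),
                                         events=[(0, True)])
            self.sv_edges.setdefault(key[0], set()).add(key)
            self.sv_edges.setdefault(key[1], set()).add(key)

        self._build(t=0, affected_l2_chunks=set(self.chunk_svs),
                    affected_svs=set(self.label_of_sv_id))

    # -- edge state ---------------------------------------------------------

    def edge_state(self, key: tuple[int, int], t: int) -> bool:
        rec = self.edges.get(key)
        return rec.state_at(t) if rec else False

    def effective_edges(self, t: int) -> Iterator[tuple[int, int]]:
        """All supervoxel edges that are ON at time t (by supervoxel ID)."""
        for key, rec in self.edges.items():
            if rec.state_at(t):
                yield key

    # -- hierarchy build / rebuild -------------------------------------------

    def _valid_nodes_at(self, layer: int, chunk, t: int) -> list[Node]:
        return [self.nodes[nid]
                for nid in self._chunk_index.get((layer, tuple(chunk)), [])
                if self.nodes[nid].valid_at(t)]

    def _l2_cross_edges(self, comp: frozenset, chunk, t: int) -> dict:
        cross: dict[int, set] = {}
        for sv in comp:
            for key in self.sv_edges.get(sv, ()):
                if not self.edges[key].state_at(t):
                    continue
                other = key[0] if key[1] == sv else key[1]
                other_chunk = self.nodes[other].chunk
                if other_chunk != chunk:
                    dl = self.divergence_layer(chunk, other_chunk)
                    cross.setdefault(dl, set()).add(key)
        return {dl: frozenset(v) for dl, v in cross.items()}

    def _ancestor_at_layer(self, sv_id: int, layer: int, t: int) -> int:
        node = self.nodes[sv_id]
        while node.layer < layer:
            node = self.nodes[self._parent_of(node, t)]
        return node.id

    def _parent_of(self, node: Node, t: int) -> int:
        idx = bisect_right(node.parents, (t, float("inf"))) - 1
        if idx < 0:
            raise NotFoundError(f"node {node.id} has no parent at t={t}")
        return node.parents[idx][1]

    def _build(self, t: int, affected_l2_chunks: set, affected_svs: set
               ) -> RebuildResult:
        """(Re)build hierarchy in the affected chunks at time t.

        A layer-2 component is re-minted iff its leaf set changed or it
        contains a supervoxel incident to an edge touched at t; higher-layer
        nodes are re-minted iff their children set changed. Replaced nodes
        expire at t; new nodes are created at t.
        """
        new_l2_ids: list[int] = []
        changed_chunks: set[tuple] = set()

        for chunk in sorted(affected_l2_chunks):
            svs = self.chunk_svs.get(chunk, [])
            uf = _UnionFind(svs)
            for sv in svs:
                for key in self.sv_edges.get(sv, ()):
                    other = key[0] if key[1] == sv else key[1]
                    if self.nodes[other].chunk == chunk and \
                            self.edges[key].state_at(t):
                        uf.union(sv, other)
            comps = sorted(uf.components(), key=min)
            existing = {frozenset(n.children): n
                        for n in self._valid_nodes_at(2, chunk, t)}
            kept: set[frozenset] = set()
            minted_here = False
            for comp in comps:
                node = existing.get(comp)
                if node is not None and not (comp & affected_svs):
                    kept.add(comp)
                    continue
                new_id = self._mint(2, chunk)
                new_node = Node(id=new_id, layer=2, chunk=chunk,
                                children=tuple(sorted(comp)), created=t,
                                cross_edges=self._l2_cross_edges(comp, chunk, t))
                self.nodes[new_id] = new_node
                self._chunk_index.setdefault((2, chunk), []).append(new_id)
                for sv in comp:
                    self.nodes[sv].parents.append((t, new_id))
                new_l2_ids.append(new_id)
                minted_here = True
            for comp, node in existing.items():
                if comp not in kept:
                    node.expired = t
                    minted_here = True
            if minted_here:
                changed_chunks.add(chunk)

        new_top: list[int] = []
        expired_top: list[int] = []
        child_changed = changed_chunks
        for layer in range(3, self.n_layers + 1):
            parent_chunks = {self.chunk_at_layer(c, 3) if layer == 3
                             else tuple(cc // self.fanout for cc in c)
                             for c in child_changed}
            # child_changed holds layer-(layer-1) chunk coords; their parents:
            layer_changed: set[tuple] = set()
            for pchunk in sorted(parent_chunks):
                children: list[Node] = []
                for off in np.ndindex(self.fanout, self.fanout, self.fanout):
                    cc = tuple(p * self.fanout + o for p, o in zip(pchunk, off))
                    children.extend(self._valid_nodes_at(layer - 1, cc, t))
                uf = _UnionFind([c.id for c in children])
                for child in children:
                    for key in child.cross_edges.get(layer, ()):
                        a, b = key
                        ra = self._ancestor_at_layer(a, layer - 1, t)
                        rb = self._ancestor_at_layer(b, layer - 1, t)
                        if ra in uf.parent and rb in uf.parent:
                            uf.union(ra, rb)
                comps = sorted(uf.components(), key=min)
                existing = {frozenset(n.children): n
                            for n in self._valid_nodes_at(layer, pchunk, t)}
                kept = set()
                minted_here = False
                for comp in comps:
                    node = existing.get(comp)
                    if node is not None:
                        kept.add(comp)
                        continue
                    new_id = self._mint(layer, pchunk)
                    cross: dict[int, set] = {}
                    for cid in comp:
                        for dl, keys in self.nodes[cid].cross_edges.items():
                            if dl > layer:
                                cross.setdefault(dl, set()).update(keys)
                    new_node = Node(id=new_id, layer=layer, chunk=pchunk,
                                    children=tuple(sorted(comp)), created=t,
                                    cross_edges={dl: frozenset(v)
                                                 for dl, v in cross.items()})
                    self.nodes[new_id] = new_node
                    self._chunk_index.setdefault((layer, pchunk), []) \
                        .append(new_id)
                    for cid in comp:
                        self.nodes[cid].parents.append((t, new_id))
                    if layer == self.n_layers:
                        new_top.append(new_id)
                    minted_here = True
                for comp, node in existing.items():
                    if comp not in kept:
                        node.expired = t
                        if layer == self.n_layers:
                            expired_top.append(node.id)
                        minted_here = True
                if minted_here:
                    layer_changed.add(pchunk)
            child_changed = layer_changed
            if not child_changed:
                break

        return RebuildResult(t=t, new_l2_ids=new_l2_ids, new_roots=new_top,
                             expired_roots=expired_top)

    def apply_edge_changes(self, added, removed, t: int) -> RebuildResult:
        """Apply edge events at time t and rebuild affected hierarchy.

        ``added``: iterable of (sv_id_a, sv_id_b, affinity, is_fake);
        ``removed``: iterable of (sv_id_a, sv_id_b). Called by the edit
        engine; supervoxel IDs, not labels.
        """
        affected_svs: set[int] = set()
        for a, b, affinity, is_fake in added:
            key = edge_key(a, b)
            rec = self.edges.get(key)
            if rec is None:
                rec = EdgeRecord(affinity=float(affinity), is_fake=is_fake)
                self.edges[key] = rec
                self.sv_edges.setdefault(key[0], set()).add(key)
                self.sv_edges.setdefault(key[1], set()).add(key)
            rec.events.append((t, True))
            affected_svs.update(key)
        for a, b in removed:
            key = edge_key(a, b)
            if key not in self.edges:
                raise NotFoundError(f"cannot remove unknown edge {key}")
            self.edges[key].events.append((t, False))
            affected_svs.update(key)
        chunks = {self.nodes[sv].chunk for sv in affected_svs}
        return self._build(t=t, affected_l2_chunks=chunks,
                           affected_svs=affected_svs)

    # -- queries ------------------------------------------------------------

    def _require_sv(self, sv_id: int) -> Node:
        node = self.nodes.get(sv_id)
        if node is None or node.layer != 1:
            raise NotFoundError(f"unknown supervoxel {sv_id}")
        return node

    def get_root(self, sv_id: int, t: int) -> int:
        """Root of a supervoxel at time t (pure parent-pointer walk)."""
        if t < 0:
            raise InvalidArgumentError(f"t must be >= 0, got {t}")
        node = self._require_sv(sv_id)
        while node.layer < self.n_layers:
            node = self.nodes[self._parent_of(node, t)]
        return node.id

    def _check_valid(self, node_id: int, t: int) -> Node:
        node = self.nodes.get(node_id)
        if node is None:
            raise NotFoundError(f"unknown node {node_id}")
        if not node.valid_at(t):
            succ = ()
            if node.layer == self.n_layers:
                try:
                    succ = tuple(self.map_roots([node_id],
                                                t_from=node.created, t_to=t))
                except Exception:
                    succ = ()
            raise StaleIDError(node_id, t, succ)
        return node

    def get_leaves(self, root_id: int, t: int, bbox=None) -> set[int]:
        """All supervoxels under a node, optionally restricted to a half-open
        voxel bounding box by octree pruning on chunk extents."""
        node = self._check_valid(root_id, t)
        if bbox is not None:
            (blo, bhi) = bbox
            if any(l >= h for l, h in zip(blo, bhi)):
                return set()

        def intersects(n: Node) -> bool:
            if bbox is None:
                return True
            lo, hi = self.chunk_extent(n.chunk, n.layer)
            return all(l < bh and bl < h for l, h, bl, bh in
                       zip(lo, hi, bbox[0], bbox[1]))

        out: set[int] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if not intersects(n):
                continue
            if n.layer == 1:
                out.add(n.id)
            else:
                stack.extend(self.nodes[c] for c in n.children)
        return out

    def get_subgraph_layer(self, root_id: int, layer: int, t: int) -> set[int]:
        """All descendants of a node at the given layer (2 = L2 IDs)."""
        node = self._check_valid(root_id, t)
        if not (1 <= layer <= node.layer):
            raise InvalidArgumentError(
                f"layer must be in [1, {node.layer}], got {layer}")
        out: set[int] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.layer == layer:
                out.add(n.id)
            else:
                stack.extend(self.nodes[c] for c in n.children)
        return out

    def get_l2_graph(self, root_id: int, t: int) -> nx.Graph:
        """Graph over the root's L2 IDs; edges from effective cross-chunk
        supervoxel edges (including fake edges added by merges)."""
        l2_ids = self.get_subgraph_layer(root_id, 2, t)
        g = nx.Graph()
        g.add_nodes_from(sorted(l2_ids))
        for l2 in sorted(l2_ids):
            for keys in self.nodes[l2].cross_edges.values():
                for a, b in sorted(keys):
                    la = self._ancestor_at_layer(a, 2, t)
                    lb = self._ancestor_at_layer(b, 2, t)
                    if la != lb and la in l2_ids and lb in l2_ids:
                        g.add_edge(la, lb)
        return g

    def roots_at(self, t: int) -> list[int]:
        top = (self.n_layers, (0, 0, 0))
        return sorted(n for n in self._chunk_index.get(top, [])
                      if self.nodes[n].valid_at(t))

    # -- lineage ------------------------------------------------------------

    def map_roots(self, roots: Iterable[int], t_from: int, t_to: int) -> set[int]:
        """Map roots across time along the lineage graph.

        Returns the (overinclusive) set of roots valid at ``t_to`` reachable
        from the inputs by walking lineage edges forward (``t_to > t_from``)
        or backward; with no intervening edits this is the identity.
        """
        for r in roots:
            if r not in self.nodes or self.nodes[r].layer != self.n_layers:
                raise NotFoundError(f"unknown root {r}")
        out: set[int] = set()
        frontier = set(roots)
        seen: set[int] = set()
        forward = t_to >= t_from
        while frontier:
            nxt: set[int] = set()
            for r in frontier:
                if r in seen:
                    continue
                seen.add(r)
                node = self.nodes[r]
                if node.valid_at(t_to):
                    out.add(r)
                    continue
                if forward:
                    edges = self.lineage.out_edges(r, data=True) \
                        if node.expired <= t_to else ()
                else:
                    edges = self.lineage.in_edges(r, data=True) \
                        if node.created > t_to else ()
                for u, v, data in edges:
                    nxt.add(v if forward else u)
            frontier = nxt
        return out

    def lineage_slice(self, root: int, t_from: int, t_to: int) -> nx.DiGraph:
        """Lineage subgraph reachable from ``root`` within [t_from, t_to]."""
        if root not in self.nodes:
            raise NotFoundError(f"unknown root {root}")
        lo, hi = min(t_from, t_to), max(t_from, t_to)
        keep = set()
        frontier = {root}
        while frontier:
            nxt = set()
            for r in frontier:
                if r in keep:
                    continue
                keep.add(r)
                for u, v, data in list(self.lineage.out_edges(r, data=True)) + \
                        list(self.lineage.in_edges(r, data=True)):
                    if lo <= data["t"] <= hi:
                        nxt.update((u, v))
            frontier = nxt - keep
        return self.lineage.subgraph(keep).copy()

    # -- edit serialization contract -----------------------------------------

    def acquire_edit_lock(self):
        if self._edit_lock:
            raise ConcurrentEditError(
                "an edit is already in progress; retry after it completes")
        self._edit_lock = True

    def release_edit_lock(self):
        self._edit_lock = False

    # -- persistence ----------------------------------------------------------

    def save(self, directory) -> None:
        """Persist as a directory: nodes CSV, edge log JSONL, compact edges,
        lineage as node-link JSON."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        rows = []
        for n in self.nodes.values():
            rows.append({
                "id": n.id, "layer": n.layer,
                "chunk_x": n.chunk[0], "chunk_y": n.chunk[1],
                "chunk_z": n.chunk[2],
                "children": " ".join(map(str, n.children)),
                "created": n.created, "expired": n.expired,
                "parents": " ".join(f"{t}:{p}" for t, p in n.parents),
                "cross_edges": json.dumps(
                    {dl: sorted(map(list, keys))
                     for dl, keys in n.cross_edges.items()}),
            })
        pd.DataFrame(rows).to_csv(d / "nodes.csv", index=False)
        (d / "lineage.json").write_text(
            json.dumps(nx.node_link_data(self.lineage, edges="links")))
        ingest_rows = []
        with open(d / "edge_log.jsonl", "w") as f:
            for key, rec in self.edges.items():
                f.write(json.dumps({
                    "sv_a": key[0], "sv_b": key[1],
                    "affinity": rec.affinity, "is_fake": rec.is_fake,
                    "events": rec.events}) + "\n")
                if not rec.is_fake:
                    ingest_rows.append((self.label_of_sv_id[key[0]],
                                        self.label_of_sv_id[key[1]],
                                        rec.affinity))
        ingest_df = pd.DataFrame(ingest_rows,
                                 columns=["sv_a", "sv_b", "affinity"])
        save_edges_binary(ingest_df, d / "ingest_edges.bin.zst")
        meta = {
            "chunk_size": self.chunk_size, "fanout": self.fanout,
            "volume_shape": self.volume_shape, "n_layers": self.n_layers,
            "clock": self.clock.now,
            "sv_id_of_label": {str(k): v
                               for k, v in self.sv_id_of_label.items()},
        }
        (d / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory, clock: Optional[LogicalClock] = None
             ) -> "ChunkedGraph":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        graph = cls(chunk_size=tuple(meta["chunk_size"]),
                    fanout=meta["fanout"],
                    volume_shape=tuple(meta["volume_shape"]), clock=clock)
        graph.clock.advance_to(meta["clock"])
        graph.sv_id_of_label = {int(k): int(v)
                                for k, v in meta["sv_id_of_label"].items()}
        graph.label_of_sv_id = {v: k for k, v in graph.sv_id_of_label.items()}
        df = pd.read_csv(d / "nodes.csv",
                         dtype={"children": str, "parents": str},
                         keep_default_na=False)
        for r in df.itertuples(index=False):
            children = tuple(int(c) for c in r.children.split()) \
                if r.children else ()
            parents = [(int(p.split(":")[0]), int(p.split(":")[1]))
                       for p in r.parents.split()] if r.parents else []
            cross = {int(dl): frozenset(tuple(k) for k in keys)
                     for dl, keys in json.loads(r.cross_edges).items()}
            node = Node(id=int(r.id), layer=int(r.layer),
                        chunk=(int(r.chunk_x), int(r.chunk_y), int(r.chunk_z)),
                        children=children, created=int(r.created),
                        expired=int(r.expired), parents=parents,
                        cross_edges=cross)
            graph.nodes[node.id] = node
            graph._chunk_index.setdefault((node.layer, node.chunk), []) \
                .append(node.id)
            _, _, counter = graph.layout.unpack(node.id)
            key = (node.layer, node.chunk)
            graph._counters[key] = max(graph._counters.get(key, 0), counter)
            if node.layer == 1:
                graph.chunk_svs.setdefault(node.chunk, []).append(node.id)
        with open(d / "edge_log.jsonl") as f:
            for line in f:
                rec = json.loads(line)
                key = (int(rec["sv_a"]), int(rec["sv_b"]))
                graph.edges[key] = EdgeRecord(
                    affinity=rec["affinity"], is_fake=rec["is_fake"],
                    events=[(int(t), bool(on)) for t, on in rec["events"]])
                graph.sv_edges.setdefault(key[0], set()).add(key)
                graph.sv_edges.setdefault(key[1], set()).add(key)
        lineage_path = d / "lineage.json"
        if lineage_path.exists():
            graph.lineage = nx.node_link_graph(
                json.loads(lineage_path.read_text()), edges="links")
        return graph
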