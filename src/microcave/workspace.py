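"""Project facade and the end-to-end demo pipeline.

A :class:`Workspace` wires a label volume, the versioned graph, the
morphology cache (subscribed to the post-edit hook), the annotation store
(bound to the supervoxel grid) and the materializer around one shared
logical clock. :func:`run_demo` exercises the whole proofreading workflow
on synthetic data and reports every invariant it checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

from . import synthetic
from .annotations import AnnotationStore
from .chunkedgraph import ChunkedGraph
from .config import LogicalClock, ProjectConfig, get_logger
from .edits import EditEngine, build_local_graph
from .errors import MicrocaveError, NoOpEditError
from .l2cache import L2Cache
from .materialize import Filter, Materializer, QuerySpec
from .skeleton import skeletonize_root, write_swc

logger = get_logger("microcave.workspace")


@dataclass
class Workspace:
    config: ProjectConfig
    vol: synthetic.LabelVolume
    gt: synthetic.GroundTruth
    graph: ChunkedGraph
    cache: L2Cache
    store: AnnotationStore
    editor: EditEngine
    materializer: Materializer

    @classmethod
    def from_synthetic(cls, config: Optional[ProjectConfig] = None,
                       shape=(48, 48, 48), n_cells: int = 20,
                       sv_size: int = 400, error_rate: float = 0.1,
                       seed: Optional[int] = None) -> "Workspace":
        config = config or ProjectConfig()
        seed = config.seed if seed is None else seed
        vol = synthetic.generate_cells(shape, n_cells, seed=seed,
                                       resolution=config.resolution)
        vol, _ = synthetic.oversegment(vol, sv_size, seed=seed + 1)
        edges, gt = synthetic.derive_edges(
            vol, error_rate, seed=seed + 2,
            within_cell_affinity=config.within_cell_affinity,
            false_merge_affinity=config.false_merge_affinity)
        return cls.assemble(config, vol, gt, edges)

    @classmethod
    def assemble(cls, config: ProjectConfig, vol, gt, edges) -> "Workspace":
        clock = LogicalClock()
        graph = ChunkedGraph.from_volume(
            vol, edges, chunk_size=config.chunk_size, fanout=config.fanout,
            layout=config.bit_layout(), clock=clock)
        cache = L2Cache(vol, graph)
        cache.populate(0)
        editor = EditEngine(graph, vol=vol,
                            fake_edge_affinity=config.fake_edge_affinity)
        editor.post_edit_hooks.append(cache.on_edit)

        def sv_resolver(point):
            label = vol.sv_at(point)
            return graph.sv_id_of_label[label] if label else None

        store = AnnotationStore(clock=clock, sv_resolver=sv_resolver)
        materializer = Materializer(store, graph)
        return cls(config=config, vol=vol, gt=gt, graph=graph, cache=cache,
                   store=store, editor=editor, materializer=materializer)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        synthetic.save_volume(self.vol, d / "volume.h5")
        self.graph.save(d / "graph")
        self.cache.save(d / "l2cache.csv")
        self.store.save(d / "tables")
        self.materializer.save_snapshots(d / "snapshots")
        self.config.to_json(d / "config.json")

    @classmethod
    def load(cls, directory) -> "Workspace":
        d = Path(directory)
        config = ProjectConfig.from_json(d / "config.json")
        vol = synthetic.load_volume(d / "volume.h5")
        clock = LogicalClock()
        graph = ChunkedGraph.load(d / "graph", clock=clock)
        cache = L2Cache(vol, graph)
        # records are derived data: recompute for every L2 node ever minted
        from .l2cache import compute_l2_features
        for n in graph.nodes.values():
            if n.layer == 2:
                cache.records[n.id] = compute_l2_features(vol, graph, n.id)
        editor = EditEngine(graph, vol=vol,
                            fake_edge_affinity=config.fake_edge_affinity)
        editor.post_edit_hooks.append(cache.on_edit)

        def sv_resolver(point):
            label = vol.sv_at(point)
            return graph.sv_id_of_label[label] if label else None

        store = AnnotationStore(clock=clock, sv_resolver=sv_resolver)
        tables_dir = d / "tables"
        if (tables_dir / "tables.json").exists():
            store.load(tables_dir)
        materializer = Materializer(store, graph)
        materializer.load_snapshots(d / "snapshots")
        return cls(config=config, vol=vol,
                   gt=synthetic.GroundTruth(sv_to_cell={}), graph=graph,
                   cache=cache, store=store, editor=editor,
                   materializer=materializer)

    # -- oracles ------------------------------------------------------------

    def oracle_partition(self, t: int) -> list[list[int]]:
        """Connected components of the effective edge set (union-find)."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.label_of_sv_id)
        g.add_edges_from(self.graph.effective_edges(t))
        return sorted(sorted(c) for c in nx.connected_components(g))

    def hierarchy_partition(self, t: int) -> list[list[int]]:
        parts: dict[int, list] = {}
        for sv in self.graph.label_of_sv_id:
            parts.setdefault(self.graph.get_root(sv, t), []).append(sv)
        return sorted(sorted(c) for c in parts.values())


# ---------------------------------------------------------------------------
# Scripted repair of injected errors
# ---------------------------------------------------------------------------

def repair_injected_errors(ws: Workspace, max_rounds: int = 10) -> dict:
    """Fix every injected error with merges and splits.

    False merges: split with *fully labeled* sides — every same-root
    supervoxel of each ground-truth cell inside the local box is a label,
    so the min cut can only sever between-cell (injected) edges. False
    splits: merge representative supervoxels of the fragmented cell.
    """
    graph, gt = ws.graph, ws.gt
    sv_id = graph.sv_id_of_label
    merges = [e for e in gt.injected_errors if e.kind == "merge"]
    n_split_ops = n_merge_ops = 0
    for _ in range(max_rounds):
        progress = False
        t_now = graph.clock.now
        for err in merges:
            a, b = sv_id[err.sv_a], sv_id[err.sv_b]
            t_now = graph.clock.now
            if graph.get_root(a, t_now) != graph.get_root(b, t_now):
                continue
            sources, sinks = _full_side_labels(ws, a, b, t_now)
            try:
                ws.editor.split(sources, sinks)
                n_split_ops += 1
                progress = True
            except MicrocaveError:
                continue
        # merge fragments of each ground-truth cell
        by_cell: dict[int, list[int]] = {}
        for lbl, cell in gt.sv_to_cell.items():
            by_cell.setdefault(cell, []).append(lbl)
        t_now = graph.clock.now
        for cell, labels in sorted(by_cell.items()):
            by_root: dict[int, list[int]] = {}
            for lbl in sorted(labels):
                by_root.setdefault(graph.get_root(sv_id[lbl], t_now), []) \
                    .append(lbl)
            groups = [v for _, v in sorted(by_root.items())]
            for other in groups[1:]:
                try:
                    ws.editor.merge(sv_id[groups[0][0]], sv_id[other[0]])
                    n_merge_ops += 1
                    progress = True
                except NoOpEditError:
                    pass
            t_now = graph.clock.now
        if _partition_matches_cells(ws, graph.clock.now):
            break
        if not progress:
            break
    return {"repair_split_ops": n_split_ops, "repair_merge_ops": n_merge_ops}


def _full_side_labels(ws: Workspace, a: int, b: int, t: int):
    """All same-root supervoxels of a's and b's cells inside the local box,
    restricted to the locally connected component of each seed."""
    from .edits import _local_svs, _pad_chunks
    graph, gt = ws.graph, ws.gt
    cell_of = {graph.sv_id_of_label[l]: c for l, c in gt.sv_to_cell.items()}
    root = graph.get_root(a, t)
    chunks = _pad_chunks(graph, [a, b])
    local = {sv for sv in _local_svs(graph, chunks)
             if graph.get_root(sv, t) == root}
    lg = build_local_graph(graph, local, t)
    sides = []
    for seed in (a, b):
        cell = cell_of[seed]
        members = {sv for sv in local if cell_of[sv] == cell}
        comp = nx.node_connected_component(lg.subgraph(members), seed)
        sides.append(sorted(comp))
    return sides[0], sides[1]


def _partition_matches_cells(ws: Workspace, t: int) -> bool:
    cells: dict[int, set] = {}
    for lbl, cell in ws.gt.sv_to_cell.items():
        cells.setdefault(cell, set()).add(ws.graph.sv_id_of_label[lbl])
    expected = sorted(sorted(c) for c in cells.values())
    return ws.hierarchy_partition(t) == expected


# ---------------------------------------------------------------------------
# Demo
# ---------------------------------------------------------------------------

def run_demo(config: Optional[ProjectConfig] = None, shape=(48, 48, 48),
             n_cells: int = 20, sv_size: int = 400, error_rate: float = 0.1,
             n_synapses: int = 30, n_queries: int = 20,
             swc_path=None) -> dict:
    """Full workflow: generate, ingest, proofread, annotate, materialize,
    time-travel query, skeletonize. Returns a JSON-serializable report of
    every invariant checked; deterministic given ``config.seed``."""
    config = config or ProjectConfig()
    rng = np.random.default_rng(config.seed + 10)
    report: dict = {"seed": config.seed}
    stage = "generate"
    try:
        ws = Workspace.from_synthetic(config, shape=shape, n_cells=n_cells,
                                      sv_size=sv_size, error_rate=error_rate)
        report["n_supervoxels"] = len(ws.graph.sv_id_of_label)
        report["n_injected_merges"] = sum(
            1 for e in ws.gt.injected_errors if e.kind == "merge")
        report["n_injected_splits"] = sum(
            1 for e in ws.gt.injected_errors if e.kind == "split")
        report["n_roots_initial"] = len(ws.graph.roots_at(0))

        stage = "annotate"
        ann = synthetic.generate_annotations(ws.vol, n_synapses,
                                             seed=config.seed + 3)
        ws.store.create_table("synapses", "synapse",
                              description="synthetic synapses",
                              resolution=config.resolution)
        ws.store.create_table("nuclei", "cell_location",
                              description="synthetic cell bodies",
                              resolution=config.resolution)
        ins = ws.store.insert("synapses", ann["synapse"])
        ws.store.insert("nuclei", ann["cell_location"])
        report["n_synapses"] = len(ins.ids)
        ws.materializer.materialize()

        stage = "proofread"
        report.update(repair_injected_errors(ws))
        t_final = ws.graph.clock.now
        report["n_edits"] = len(ws.graph.operations)
        report["final_partition_matches_ground_truth"] = \
            _partition_matches_cells(ws, t_final)

        stage = "annotation-churn"
        if ins.ids:
            doomed = [int(i) for i in
                      rng.choice(ins.ids, size=min(3, len(ins.ids)),
                                 replace=False)]
            ws.store.delete("synapses", doomed)
            survivor = next(i for i in ins.ids if i not in doomed)
            ws.store.update("synapses", survivor, {"size": 123.456})
        ws.materializer.materialize()

        stage = "partition-oracle"
        mismatches = 0
        for t in range(ws.graph.clock.now + 1):
            if ws.oracle_partition(t) != ws.hierarchy_partition(t):
                mismatches += 1
        report["partition_oracle_mismatches"] = mismatches
        report["n_timestamps_checked"] = ws.graph.clock.now + 1

        stage = "synapse-roots"
        t_now = ws.graph.clock.now
        snap = ws.materializer.materialize(t_now)
        syn_df = snap.tables["synapses"]
        correct = 0
        for row in syn_df.itertuples(index=False):
            pre_cell = ws.gt.sv_to_cell[
                ws.graph.label_of_sv_id[int(row.pre_pt_supervoxel)]]
            post_cell = ws.gt.sv_to_cell[
                ws.graph.label_of_sv_id[int(row.post_pt_supervoxel)]]
            pre_ok = _root_is_cell(ws, int(row.pre_pt_root), pre_cell, t_now)
            post_ok = _root_is_cell(ws, int(row.post_pt_root), post_cell, t_now)
            correct += pre_ok and post_ok
        report["synapse_root_accuracy"] = (
            correct / len(syn_df) if len(syn_df) else 1.0)

        stage = "live-queries"
        mismatch = 0
        for _ in range(n_queries):
            t_q = int(rng.integers(0, ws.graph.clock.now + 1))
            roots = ws.graph.roots_at(t_q)
            flt = []
            kind = rng.integers(0, 3)
            if kind == 0 and roots:
                pick = [int(r) for r in
                        rng.choice(roots, size=min(2, len(roots)),
                                   replace=False)]
                flt = [Filter("pre_pt_root", "in", pick)]
            elif kind == 1 and roots:
                flt = [Filter("post_pt_root", "eq",
                              int(rng.choice(roots)))]
            bbox = {}
            if rng.random() < 0.5:
                lo = rng.integers(0, max(1, shape[0] // 2), size=3)
                hi = lo + rng.integers(8, shape[0], size=3)
                bbox = {"pre_pt": (tuple(int(v) for v in lo),
                                   tuple(int(v) for v in hi))}
            spec = QuerySpec(table="synapses", t_query=t_q, filters=flt,
                             bbox_filters=bbox)
            live = ws.materializer.live_query(spec)
            fresh = Materializer(ws.store, ws.graph)
            fresh.materialize(t_q)
            expected = fresh.query_snapshot(spec)
            if not _same_rows(live.df, expected.df):
                mismatch += 1
        report["live_vs_materialized_mismatches"] = mismatch
        report["n_live_queries"] = n_queries

        stage = "skeletonize"
        t_now = ws.graph.clock.now
        roots = ws.graph.roots_at(t_now)
        sizes = {r: len(ws.graph.get_leaves(r, t_now)) for r in roots}
        big = max(sorted(roots), key=lambda r: sizes[r])
        stats = ws.cache.segment_stats(big, t_now)
        rep = stats.per_l2.iloc[0]
        skel = skeletonize_root(ws.graph, ws.cache, big, t_now,
                                (rep.rep_x, rep.rep_y, rep.rep_z))
        report["skeleton"] = {
            "root": int(big), "n_vertices": skel.n_vertices,
            "n_edges": len(skel.edges), "is_tree": skel.is_tree(),
            "invalidation_total": len(skel.invalidation_map) ==
            len(ws.graph.get_subgraph_layer(big, 2, t_now)),
        }
        if swc_path is not None:
            write_swc(skel, swc_path, cache=ws.cache)
    except MicrocaveError as e:
        raise RuntimeError(f"demo failed at stage {stage!r}: {e}") from e
    return report


def _root_is_cell(ws: Workspace, root: int, cell: int, t: int) -> bool:
    leaves = {ws.graph.label_of_sv_id[sv]
              for sv in ws.graph.get_leaves(root, t)}
    cell_svs = {l for l, c in ws.gt.sv_to_cell.items() if c == cell}
    return leaves == cell_svs


def _same_rows(a, b) -> bool:
    if len(a) != len(b):
        return False
    if len(a) == 0:
        return True
    cols = sorted(set(a.columns) & set(b.columns))
    id_cols = [c for c in cols if c == "id" or c.startswith("id_")] or cols
    aa = a[cols].sort_values(id_cols).reset_index(drop=True)
    bb = b[cols].sort_values(id_cols).reset_index(drop=True)
    return aa.equals(bb)
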