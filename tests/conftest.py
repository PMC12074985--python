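import numpy as np
import pandas as pd
import pytest

import microcave as mc
from microcave.workspace import Workspace


@pytest.fixture(scope="session")
def make_workspace():
    """Factory for fresh synthetic workspaces (mutating tests need their own)."""

    def _make(seed=0, shape=(32, 32, 32), n_cells=8, sv_size=300,
              error_rate=0.1, chunk_size=(16, 16, 16)):
        config = mc.ProjectConfig(seed=seed, chunk_size=chunk_size)
        return Workspace.from_synthetic(config, shape=shape, n_cells=n_cells,
                                        sv_size=sv_size, error_rate=error_rate)

    return _make


@pytest.fixture()
def ws(make_workspace):
    return make_workspace()


def make_mask_volume(mask: np.ndarray, resolution=(1.0, 1.0, 1.0)
                     ) -> mc.LabelVolume:
    """Volume whose single supervoxel is exactly ``mask``."""
    sv = np.zeros(mask.shape, dtype=np.int64)
    sv[mask] = 1
    return mc.LabelVolume(shape=mask.shape, resolution=tuple(resolution),
                          cell_labels=sv.astype(np.int32),
                          supervoxel_labels=sv)


def single_node_graph(vol: mc.LabelVolume, chunk_size=None) -> mc.ChunkedGraph:
    chunk_size = chunk_size or vol.shape
    empty = pd.DataFrame(columns=["sv_a", "sv_b", "affinity"])
    return mc.ChunkedGraph.from_volume(vol, empty, chunk_size=chunk_size)


def tube_volume(k=5, chunk=8, resolution=(1.0, 1.0, 1.0)):
    """Straight tube crossing k chunks, one supervoxel per chunk."""
    shape = (k * chunk, chunk, chunk)
    sv = np.zeros(shape, dtype=np.int64)
    for i in range(k):
        sv[i * chunk:(i + 1) * chunk] = i + 1
    vol = mc.LabelVolume(shape=shape, resolution=tuple(resolution),
                         cell_labels=(sv > 0).astype(np.int32),
                         supervoxel_labels=sv)
    edges = pd.DataFrame([(i, i + 1, 0.9) for i in range(1, k)],
                         columns=["sv_a", "sv_b", "affinity"])
    return vol, edges


def random_edits(workspace, n, rng, allow_fail=True):
    """Apply n random merges/splits (where applicable); returns ops applied."""
    ids = sorted(workspace.graph.label_of_sv_id)
    ops = []
    for _ in range(n):
        a, b = (int(v) for v in rng.choice(ids, 2, replace=False))
        t = workspace.graph.clock.now
        try:
            if workspace.graph.get_root(a, t) != workspace.graph.get_root(b, t):
                ops.append(workspace.editor.merge(a, b))
            else:
                ops.append(workspace.editor.split([a], [b]))
        except mc.errors.MicrocaveError:
            if not allow_fail:
                raise
    return ops


def oracle_vs_hierarchy_ok(workspace, t) -> bool:
    return workspace.oracle_partition(t) == workspace.hierarchy_partition(t)


# ---------------------------------------------------------------------------
# Randomized edit/annotation/snapshot history driver (shared with the
# time-travel acceptance property)
# ---------------------------------------------------------------------------

def run_random_history(seed, shape=(32, 32, 32), n_cells=6, sv_size=250,
                       error_rate=0.1, n_events=20, n_queries=6):
    """Interleave edits, inserts, deletes, updates and snapshots, then check
    live queries of every filter shape against a fresh materialization.

    Returns (mismatches, queries_run).
    """
    from microcave.materialize import Filter, Materializer, QuerySpec
    from microcave.workspace import _same_rows

    rng = np.random.default_rng(seed)
    w = Workspace.from_synthetic(
        mc.ProjectConfig(seed=int(seed)), shape=shape, n_cells=n_cells,
        sv_size=sv_size, error_rate=error_rate)
    ann = mc.generate_annotations(w.vol, 15, seed=int(seed) + 1)
    w.store.create_table("synapses", "synapse")
    w.store.create_table("nuclei", "cell_location")
    w.store.create_table("types", "cell_type_reference",
                         reference_target="nuclei")
    syn_ids = w.store.insert("synapses", ann["synapse"]).ids
    nuc_ids = w.store.insert("nuclei", ann["cell_location"]).ids
    w.store.insert("types", [
        {"target_id": i, "cell_type": rng.choice(["pyr", "basket"])}
        for i in nuc_ids])
    w.materializer.materialize()

    ids = sorted(w.graph.label_of_sv_id)
    for _ in range(n_events):
        kind = rng.choice(["edit", "edit", "insert", "delete", "update",
                           "snapshot"])
        t = w.graph.clock.now
        if kind == "edit":
            random_edits(w, 1, rng)
        elif kind == "insert" and ann["synapse"]:
            row = ann["synapse"][int(rng.integers(len(ann["synapse"])))]
            syn_ids += w.store.insert("synapses", [dict(row)]).ids
        elif kind == "delete":
            alive = [i for i in syn_ids
                     if w.store.tables["synapses"].rows[i].visible_at(t)]
            if alive:
                w.store.delete("synapses",
                               [int(rng.choice(alive))])
        elif kind == "update":
            alive = [i for i in syn_ids
                     if w.store.tables["synapses"].rows[i].visible_at(t)]
            if alive:
                new = w.store.update("synapses", int(rng.choice(alive)),
                                     {"size": float(rng.uniform(1, 100))})
                syn_ids.append(new)
        elif kind == "snapshot":
            w.materializer.materialize()

    mismatches = 0
    queries = 0
    t_max = w.graph.clock.now
    shapes = ["root_in", "eq", "bbox", "join", "plain", "not_in"]
    for qi in range(n_queries):
        t_q = int(rng.integers(0, t_max + 1))
        shape_kind = shapes[qi % len(shapes)]
        roots = w.graph.roots_at(t_q)
        filters, bbox = [], {}
        if shape_kind == "root_in" and roots:
            pick = [int(r) for r in
                    rng.choice(roots, size=min(2, len(roots)), replace=False)]
            filters = [Filter("pre_pt_root", "in", pick)]
        elif shape_kind == "eq" and roots:
            filters = [Filter("post_pt_root", "eq", int(rng.choice(roots)))]
        elif shape_kind == "not_in" and roots:
            filters = [Filter("pre_pt_root", "not_in",
                              [int(rng.choice(roots))])]
        elif shape_kind == "bbox":
            lo = rng.integers(0, shape[0] // 2, size=3)
            hi = lo + rng.integers(8, shape[0], size=3)
            bbox = {"pre_pt": (tuple(int(v) for v in lo),
                               tuple(int(v) for v in hi))}
        fresh = Materializer(w.store, w.graph)
        fresh.materialize(t_q)
        if shape_kind == "join":
            spec_a = QuerySpec(table="types", t_query=t_q)
            spec_b = QuerySpec(table="nuclei", t_query=t_q)
            live = w.materializer.join_query(spec_a, spec_b,
                                             ("target_id", "id"), live=True)
            expected = fresh.join_query(spec_a, spec_b, ("target_id", "id"),
                                        live=False)
        else:
            spec = QuerySpec(table="synapses", t_query=t_q, filters=filters,
                             bbox_filters=bbox)
            live = w.materializer.live_query(spec)
            expected = fresh.query_snapshot(spec)
        queries += 1
        if not _same_rows(live.df, expected.df):
            mismatches += 1
    return mismatches, queries
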