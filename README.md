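# microcave

A desk-scale, fully versioned supervoxel graph for connectomics
proofreading and analysis. Dense electron-microscopy reconstructions are
delivered as an *oversegmentation*: atomic groups of voxels (supervoxels)
plus an affinity-weighted adjacency graph. A putative cell is a connected
component of the "ON" edges, and proofreading consists of merge and split
edits to that graph while analyses — synapse tables, morphology, skeletons —
keep running against it concurrently. `microcave` implements the
algorithmic core of such a system as an ordinary Python library: every edit
is timestamped and every query can be answered *as of* any past timestamp.

It is aimed at people who want to study, test, or teach these algorithms on
volumes that fit in memory, with the whole pipeline — synthetic data with
known ground truth, edits, feature caching, skeletonization, annotation
queries — reproducible from a single seed.

## What is inside

- **`synthetic`** — watershed-grown ground-truth cells, supervoxel
  partitions, affinity edge lists with *injected* false merges and false
  splits, and synapse-like two-point annotations. Ground truth is retained
  as the oracle for everything else.
- **`chunkedgraph`** — the versioned hierarchy. The volume is tiled into
  chunks; layer-2 nodes are per-chunk connected components of the effective
  edge set, and each higher layer merges `fanout`³ child chunks via
  cross-chunk edges up to a single top chunk whose nodes are the *roots*
  (cells). NodeIDs pack `[layer | chunk x | y | z | counter]` into 64 bits.
  Nodes carry validity intervals `[created, expired)`, so
  `get_root(supervoxel, t)`, bounded `get_leaves(root, t, bbox)` (with
  octree pruning) and the L2-graph are all time-travel queries.
- **`edits`** — merges (reactivating stored OFF edges where possible,
  otherwise inserting a high-affinity *fake edge*), atomic multimerges, and
  splits: user labels are expanded along `-log(affinity)` shortest paths,
  then a max-flow min-cut (capacity = affinity) removes the canonical
  source-side cut. Only chunks touching affected edges are rebuilt; expired
  roots link to their successors in a lineage graph.
- **`l2cache`** — per-L2-node morphology (voxel count, volume, shift-method
  surface area, EDT statistics, representative coordinate, principal axes,
  chunk-contact face counts), recomputed after each edit for exactly the new
  L2 IDs.
- **`skeleton`** — graph-based TEASAR over the L2-graph: repeatedly trace
  the geodesically farthest vertex to the skeleton and invalidate vertices
  within distance `d`, recording a total invalidation map used to attach
  synapses and features to skeleton vertices; SWC export.
- **`annotations` / `materialize`** — schema-driven tables whose bound
  spatial points are automatically bound to supervoxels; virtual deletes and
  linked updates; snapshots with resolved root IDs; and *live queries* at
  arbitrary timestamps via the lineage-translated delta algorithm.
- **`workspace` / `cli`** — one facade wiring everything to a shared logical
  clock, plus the `microcave` command-line tool.

## Worked example

The demo runs the whole workflow: generate a 48³ volume with 20 cells and a
10% error rate, ingest it, insert synthetic synapse/cell-body annotations,
repair every injected error with scripted merges and splits, snapshot,
run live queries at random timestamps against fresh materializations, and
skeletonize the largest segment.

```python
import json
import microcave as mc

report = mc.run_demo(mc.ProjectConfig(seed=1))
print(json.dumps(report, indent=2))
```

prints

```json
{
  "seed": 1,
  "n_supervoxels": 233,
  "n_injected_merges": 64,
  "n_injected_splits": 90,
  "n_roots_initial": 1,
  "n_synapses": 30,
  "repair_split_ops": 20,
  "repair_merge_ops": 0,
  "n_edits": 20,
  "final_partition_matches_ground_truth": true,
  "partition_oracle_mismatches": 0,
  "n_timestamps_checked": 25,
  "synapse_root_accuracy": 1.0,
  "live_vs_materialized_mismatches": 0,
  "n_live_queries": 20,
  "skeleton": {
    "root": 288230376151711764,
    "n_vertices": 2,
    "n_edges": 1,
    "is_tree": true,
    "invalidation_total": true
  }
}
```

Reading it: the 64 injected false merges initially fuse everything into one
root; 20 splits (the false splits here did not disconnect any cell, so no
repair merges were needed) restore the exact ground-truth partition
(`final_partition_matches_ground_truth`). The hierarchy agrees with a
union-find over the edge log at **all 25 timestamps**, every synapse's
pre/post root matches its ground-truth cell, and all 20 live queries at
random past timestamps equal a fresh materialization at that time. The same
seed reproduces this report bit for bit.

The same pipeline is scriptable from the shell:

```bash
microcave generate --shape 48,48,48 --n-cells 20 --error-rate 0.1 \
    --seed 1 --out ws/
microcave root --workspace ws --sv 17 --t 0
microcave merge --workspace ws --points "10,4,12;11,9,3"
microcave materialize --workspace ws
microcave query --workspace ws --table synapses --t 3 --live
microcave skeletonize --workspace ws --root <root-id> --t 3 \
    --root-point 24,24,24 --out cell.swc
microcave demo --seed 1 --out report.json
```

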