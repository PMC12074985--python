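# Methods

This note documents the model behind `microcave`, the conventions chosen
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## The versioned supervoxel graph

The segmentation is a pair (supervoxel label grid, affinity edge list). The
*effective edge set at time t* is: ingest edges, plus edges added by merges
("fake" edges, or reactivated stored edges), minus edges removed by splits,
each evaluated against a timestamped event log. A cell segment at time t is
a connected component of this set.

The hierarchy is a spatially chunked index of those components. Layer-2
chunks tile the volume (`chunk_size`, default 16³ voxels); a layer-2 (L2)
node is a connected component of effective edges restricted to one chunk.
Layer k+1 groups `fanout`³ (default 2³) layer-k chunks and unions children
connected by cross-chunk edges that first become internal at that layer.
The top layer has a single chunk; its nodes are the roots. A supervoxel is
assigned to the chunk containing its representative voxel (lexicographic
minimum of its foreground voxels) and is never split across chunks.

**Edge state is the ground truth; the hierarchy is derived.** Every node
has `[created, expired)` validity and a history of parent pointers, so
`get_root(sv, t)` is a pure walk. The master correctness property — checked
in the tests and the acceptance script at every recorded timestamp — is
that the root partition always equals union-find over the effective edge
set. (A production system can instead infer edge state from the hierarchy;
keeping the explicit log is what makes the equivalence checkable here.)

**Timestamps** are a strictly increasing logical clock shared by graph
edits and annotation events; 0 is ingest. A wall-clock mapping can be
layered on, but an integer clock makes histories exactly replayable.

**NodeIDs** pack `[layer:8 | x:12 | y:12 | z:12 | counter:20]` into 64
bits (configurable). Counters allocate monotonically per (layer, chunk) and
IDs are never reused, so expired IDs remain permanently resolvable.

## Edits

*Merge.* The local box is the union of the labeled supervoxels' chunks
padded by one layer-2 chunk per direction (the box size is a convention;
edits are local but no particular extent is canonical). If OFF edges exist
between the two components inside the box, all of them are reactivated —
merging across a previous split restores the stored edges. Otherwise one
fake edge joins the two selected supervoxels with affinity/capacity 10⁶, so
user-asserted connections are cut only when nothing cheaper exists.
*Multimerge* applies several pairs at one timestamp; pairs already
connected through earlier pairs are dropped, and the resulting partition is
order-independent.

*Split.* Source/sink label sets are expanded along shortest paths under
weight `max(-log(min(affinity, 1)), 0)`, which prefers high-affinity
corridors; expansion must leave the sides disjoint or the split is rejected
as ambiguous. The cut is a max-flow min-cut with capacity = affinity on an
antiparallel-arc digraph with super source/sink. The returned cut is the
source-side residual reachability partition of a true max flow
(Edmonds–Karp), with a relative tolerance of 1e-9 on residual capacities —
note that partition extraction via exact `flow == capacity` tests is
numerically unreliable with float capacities. This makes the cut canonical
and deterministic; jittering labels within their supervoxels cannot change
it. A split may leave one root when the component remains connected outside
the local box; that is the intended local semantics.

*Incremental rebuild.* Only chunks containing an endpoint of a touched edge
are recomputed. An L2 component is re-minted iff its leaf set changed *or*
it contains an endpoint of a touched edge (the second clause covers
cross-chunk edges that change connectivity or surface accounting without
changing membership). At higher layers a node is re-minted iff its children
set changed. Replaced nodes expire at the edit's timestamp; unchanged
siblings keep their IDs and only gain a new parent pointer. Old roots are
linked to every new root sharing at least one supervoxel in the lineage
graph; `map_roots` walks those links in either direction and returns the
deliberately overinclusive related set.

Edits are serialized by a per-graph lock; a concurrent edit raises a
retryable error. An edit either fully applies or leaves no trace.

## L2 morphology cache

Features are computed on the binarized mask of an L2 node's supervoxels
(bounding box plus a one-voxel halo):

- voxel count; volume = count x rx·ry·rz (default resolution (8, 8, 40) nm);
- **area by the shift method**: shift the mask along each axis in both
  directions and count faces whose neighbour is outside the object, scaled
  by the per-orientation face area. Voxel face counting systematically
  overestimates smooth surfaces (asserted in tests as area ≥ the
  equal-volume sphere's area) — smoothed areas are deliberately out of
  scope;
- EDT mean/max with anisotropic sampling = resolution; the representative
  coordinate is the EDT argmax (ties: lexicographic minimum), guaranteed to
  lie on the object;
- principal axes from the eigendecomposition of the physical-coordinate
  covariance, eigenvalues descending, each axis's sign fixed by making its
  largest-magnitude component positive.

**Same-object convention.** A face is *not* exposed when the neighbouring
voxel belongs to a supervoxel connected to the node by one of its effective
cross-chunk edges; those faces are tallied per direction in
`face_contacts`. Consequently a record is a pure function of (leaf set,
effective incident edges), both frozen when the node is minted — any edit
changing either re-mints the node — so incremental recomputation of exactly
each edit's new L2 IDs equals a from-scratch computation, and the summed
area of a segment is independent of the chunking. Faces between same-root
supervoxels that touch spatially but share no graph edge count as surface
on both sides (a documented overestimate); dataset-boundary faces count as
surface. Expired records are retained for historical queries.

## Skeletonization

The L2-graph (vertices = a root's L2 nodes at their cached representative
coordinates, edges = cross-chunk connectivity incl. fake edges, weights =
Euclidean distance in nm) is skeletonized by the TEASAR recipe generalized
to graphs: root = vertex nearest a user point; repeat {take the
geodesically farthest uninvalidated vertex from the root, add its shortest
path to the current skeleton, invalidate every vertex within geodesic
distance `d` of the new path and record its nearest path vertex} until all
vertices are invalidated. Invalidation distance is measured along the graph
(not Euclidean), because the graph is the topology being summarized.
Default `d` = 3x the median edge weight, which absorbs the short spurs
chunking introduces; all ties (farthest vertex, nearest source) break on
the smaller packed NodeID, so skeletons are bit-stable. The result is
always a tree, and the invalidation map is total, which is what routes
synapses (supervoxel → L2 → skeleton vertex) and per-vertex feature sums
(which conserve segment totals exactly). SWC export uses `edt_max` as the
vertex radius. Disconnected L2-graphs cannot occur for a valid root and are
treated as an internal error.

## Annotations and time travel

Tables are defined by JSON schemas; the key field type is the *bound
spatial point*, a voxel coordinate bound at insert time to the supervoxel
underneath it (null for background clicks — such rows are excluded from
root filters but returned by other queries; they are never re-bound because
supervoxels are immutable). Reference schemas carry a `target_id` into
another table; orphaned reference rows are flagged at query time, not
cascaded. Deletes are virtual timestamps, updates are delete+insert with a
`superseded_by` link, and all timestamps share the graph's clock, so the
visible set at any t is a pure function of the log — visible rows are
presented *as of* t (not yet deleted, not yet superseded).

*Materialization* freezes visible rows with roots resolved at the snapshot
time. A *live query* at arbitrary t picks the closest snapshot (ties prefer
the past), maps root filters through the lineage graph (equality becomes
inclusion; negative filters cannot be translated soundly through an
overinclusive map, so they are enforced only in the final step),
re-resolves expired roots through cached supervoxels, patches annotation
rows added/removed between snapshot and query time (meanings inverted when
the snapshot is in the future; skipped when the table's last-modified time
precedes both), and re-applies the original root filters. Results truncate
at `row_limit` (default 500,000) with an explicit flag. The master property
— live query equals a fresh materialization at the same t, for root-set,
equality, negative, bounding-box, plain and join queries — is exercised
over 100+ randomized interleaved histories.

## The synthetic generator

Cells are grown by marker-based watershed on a jittered
distance-from-markers field, giving balanced, 6-connected regions (one
extra marker becomes background); supervoxels are grown the same way inside
each cell. Within-cell adjacencies get affinity N(0.9, 0.05) clipped to
(0, 1]; a fraction `error_rate` of them is withheld (false splits). A
fraction `error_rate` of between-cell adjacencies is emitted with affinity
N(0.3, 0.1) (false merges). These defaults make min cuts prefer the
injected error edges — the property the split tests check. Synapses sample
cell-cell interface voxel pairs; cell bodies sit at each cell's EDT argmax.

What this does *not* emulate: realistic neuron morphology (watershed blobs
are compact, so L2-graphs are shallow and synthetic skeletons are small —
skeleton topology is therefore additionally tested on constructed path/Y/
spur graphs), realistic affinity error structure, supervoxels spanning
chunk boundaries by design rather than accident, and any statement about
real datasets' error statistics. Passing tests show the algorithms are
correct under the stated model, not that the generator matches any
particular reconstruction pipeline.

## Problem sizes and numerics

The randomized benchmarks run at desk scale by choice: partition checks use
64³ volumes (~50 cells, ~500 supervoxels, error rate 0.1) with 50 applied
edits per graph across 100 graphs in the test suite (25 in the acceptance
script); min-cut optimality is checked against an exhaustive bipartition
oracle on 1,000 graphs with ≤ 12 edges; the time-travel equivalence runs
100 randomized histories on 32³ volumes in the suite (50 in the script).
Affinities are clipped to [1e-3, 1]; fake edges use 10⁶; residual
reachability uses a 1e-9 relative tolerance. All randomness flows from
explicit integer seeds and every reported number is recomputed at run time.

## Known limitations

- Storage is a local directory (HDF5 + CSV/JSON lines + zstd-compressed
  arrays); there is no server, no distributed locking, and no permission
  model.
- Supervoxels are atomic: edits below the supervoxel level are out of
  scope, as are meshes and mesh-derived measurements.
- The per-chunk area convention (cross-edge partners are interior) is a
  choice; other systems may count chunk-boundary faces differently.
- `get_leaves` bbox pruning filters by chunk extent, not by voxel-exact
  intersection of supervoxel masks — matching the octree semantics, a
  supervoxel is returned iff its chunk intersects the box.
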