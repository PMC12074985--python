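"""Snapshots with resolved root IDs and arbitrary-time-point queries.

*Materialization* freezes each table's visible rows at a timestamp and adds,
for every bound spatial point, the root segment ID resolved through the
versioned graph at that timestamp (``{field}_root``). Analyses filter on
those columns — "all synapses whose presynaptic root is X".

A *live query* answers the same filtered query at an arbitrary timestamp
``t_q`` without a snapshot at ``t_q``, by the delta algorithm:

1. pick the snapshot closest in time (ties prefer the past);
2. translate root-ID filters to the snapshot time through the lineage graph
   (an overinclusive set; equality filters become inclusion filters);
3. run the translated query on the snapshot;
4. re-resolve roots that expired by ``t_q`` via the cached supervoxels;
5. scan the live store for rows added/removed between the snapshot and
   ``t_q`` (meaning inverted when the snapshot lies in the future), skipping
   segment-ID filters, unless the table was last modified before both times;
6. resolve those rows' roots at ``t_q``;
7. drop deleted rows from the snapshot result, append added rows;
8. re-apply the original root filters at ``t_q``.

Rows whose bound point has a null supervoxel (background clicks) are never
matched by root filters but are returned by non-root queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Optional

import json
import numpy as np
import pandas as pd

from .annotations import AnnotationStore
from .chunkedgraph import ChunkedGraph
from .errors import InvalidArgumentError, InvalidFilterError

DEFAULT_ROW_LIMIT = 500_000


# ---------------------------------------------------------------------------
# Query specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Filter:
    column: str
    op: Literal["in", "not_in", "eq", "range"]
    value: object     # sequence for in/not_in, scalar for eq, (lo, hi) for range


@dataclass
class QuerySpec:
    table: str
    t_query: int
    filters: list[Filter] = dc_field(default_factory=list)
    # point field name -> (lo, hi) half-open voxel box
    bbox_filters: dict[str, tuple] = dc_field(default_factory=dict)
    row_limit: int = DEFAULT_ROW_LIMIT

    def __post_init__(self):
        if self.row_limit <= 0:
            raise InvalidArgumentError("row_limit must be > 0")


@dataclass
class QueryResult:
    df: pd.DataFrame
    truncated: bool = False


@dataclass
class Snapshot:
    t_snap: int
    tables: dict[str, pd.DataFrame]


def _root_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.endswith("_root")]


def _apply_filters(df: pd.DataFrame, filters, bbox_filters) -> pd.DataFrame:
    """Conjunctive filter application; root filters never match null
    supervoxel rows."""
    mask = pd.Series(True, index=df.index)
    for f in filters:
        if f.column not in df.columns:
            raise InvalidFilterError(f"unknown column {f.column!r}")
        col = df[f.column]
        if f.op == "in":
            m = col.isin(list(f.value))
        elif f.op == "not_in":
            m = ~col.isin(list(f.value))
        elif f.op == "eq":
            m = col == f.value
        elif f.op == "range":
            lo, hi = f.value
            m = (col >= lo) & (col < hi)
        else:
            raise InvalidFilterError(f"unknown filter op {f.op!r}")
        if f.column.endswith("_root"):
            m = m & col.notna()
        mask &= m.fillna(False)
    for pt, (lo, hi) in bbox_filters.items():
        for ax, l, h in zip("xyz", lo, hi):
            c = f"{pt}_{ax}"
            if c not in df.columns:
                raise InvalidFilterError(f"unknown point column {pt!r}")
            mask &= (df[c] >= l) & (df[c] < h)
    return df[mask]


# ---------------------------------------------------------------------------
# Materializer
# ---------------------------------------------------------------------------

class Materializer:
    def __init__(self, store: AnnotationStore, graph: ChunkedGraph):
        self.store = store
        self.graph = graph
        self.snapshots: list[Snapshot] = []

    # -- snapshot creation --------------------------------------------------

    def _resolve_roots(self, df: pd.DataFrame, bound_fields, t: int
                       ) -> pd.DataFrame:
        df = df.copy()
        for f in bound_fields:
            svs = df[f"{f}_supervoxel"]
            roots = [self.graph.get_root(int(sv), t) if pd.notna(sv) else pd.NA
                     for sv in svs]
            df[f"{f}_root"] = pd.array(roots, dtype="Int64")
        return df

    def materialize(self, t_snap: Optional[int] = None) -> Snapshot:
        """Freeze all tables at ``t_snap`` with resolved root IDs."""
        t_snap = self.store.clock.now if t_snap is None else t_snap
        if t_snap > self.store.clock.now:
            raise InvalidArgumentError(
                f"cannot materialize the future (t={t_snap})")
        tables = {}
        for name, table in self.store.tables.items():
            df = self.store.to_dataframe(name, t_snap)
            df = self._resolve_roots(df, table.schema.bound_point_fields,
                                     t_snap)
            tables[name] = df
        snap = Snapshot(t_snap=t_snap, tables=tables)
        self.snapshots.append(snap)
        return snap

    def _closest_snapshot(self, t: int) -> Snapshot:
        if not self.snapshots:
            raise InvalidArgumentError("no materialized snapshots exist")
        return min(self.snapshots,
                   key=lambda s: (abs(s.t_snap - t), s.t_snap > t))

    # -- snapshot queries ---------------------------------------------------

    def query_snapshot(self, spec: QuerySpec,
                       snapshot: Optional[Snapshot] = None) -> QueryResult:
        snapshot = snapshot or self._closest_snapshot(spec.t_query)
        if snapshot.t_snap != spec.t_query:
            raise InvalidArgumentError(
                f"snapshot is at t={snapshot.t_snap}, query at t={spec.t_query}; "
                "use live_query")
        if spec.table not in snapshot.tables:
            raise InvalidFilterError(f"unknown table {spec.table!r}")
        df = _apply_filters(snapshot.tables[spec.table], spec.filters,
                            spec.bbox_filters)
        return self._limit(df, spec.row_limit)

    @staticmethod
    def _limit(df: pd.DataFrame, row_limit: int) -> QueryResult:
        if len(df) > row_limit:
            return QueryResult(df.iloc[:row_limit].reset_index(drop=True),
                               truncated=True)
        return QueryResult(df.reset_index(drop=True), truncated=False)

    # -- live (delta) queries -----------------------------------------------

    def live_query(self, spec: QuerySpec) -> QueryResult:
        """Query at an arbitrary timestamp via the nearest snapshot."""
        t_q = spec.t_query
        if t_q < 0:
            raise InvalidArgumentError("t_query must be >= 0")
        snap = self._closest_snapshot(t_q)
        table = self.store._table(spec.table)
        bound_fields = table.schema.bound_point_fields

        root_filters = [f for f in spec.filters if f.column.endswith("_root")]
        other_filters = [f for f in spec.filters
                         if not f.column.endswith("_root")]

        # (2) translate root filters through the lineage graph
        translated = []
        for f in root_filters:
            if f.op in ("in", "eq"):
                ids = [f.value] if f.op == "eq" else list(f.value)
                mapped: set[int] = set()
                for r in ids:
                    mapped |= self.graph.map_roots([int(r)], t_from=t_q,
                                                   t_to=snap.t_snap)
                translated.append(Filter(f.column, "in", sorted(mapped)))
            # not_in cannot be translated soundly through an overinclusive
            # map; it is skipped here and enforced in step (8)

        # (3) translated query on the snapshot
        if spec.table not in snap.tables:
            raise InvalidFilterError(f"unknown table {spec.table!r}")
        df = _apply_filters(snap.tables[spec.table],
                            translated + other_filters, spec.bbox_filters)

        # (4) re-resolve roots that are no longer valid at t_q
        df = self._refresh_roots(df, bound_fields, t_q)

        # (5)-(7) annotation deltas from the live store
        if table.last_modified > min(snap.t_snap, t_q):
            lo, hi = sorted((snap.t_snap, t_q))
            future = snap.t_snap > t_q
            added_rows, removed_ids = [], set()
            for row in table.rows.values():
                if not future:
                    if lo < row.created <= hi and row.visible_at(t_q):
                        added_rows.append(row.id)
                    if lo < row.deleted <= hi:
                        removed_ids.add(row.id)
                else:
                    if lo < row.deleted <= hi and row.visible_at(t_q):
                        added_rows.append(row.id)
                    if lo < row.created <= hi:
                        removed_ids.add(row.id)
            if removed_ids:
                df = df[~df["id"].isin(removed_ids)]
            if added_rows:
                live = self.store.to_dataframe(spec.table, t_q)
                live = live[live["id"].isin(added_rows)]
                # (6) segment-ID filters are skipped in the live scan
                live = _apply_filters(live, other_filters, spec.bbox_filters)
                live = self._resolve_roots(live, bound_fields, t_q)
                df = pd.concat([df, live], ignore_index=True) if len(df) else live

        # (8) original root filters at t_q (incl. not_in)
        df = _apply_filters(df, root_filters, {})
        df = df.sort_values("id").reset_index(drop=True)
        if table.schema.is_reference and "orphaned" in df.columns and len(df):
            target = self.store._table(table.metadata.reference_target)
            df["orphaned"] = [
                not (tid in target.rows and target.rows[tid].visible_at(t_q))
                for tid in df["target_id"]]
        return self._limit(df, spec.row_limit)

    def _refresh_roots(self, df: pd.DataFrame, bound_fields, t_q: int
                       ) -> pd.DataFrame:
        df = df.copy()
        for f in bound_fields:
            col = f"{f}_root"
            if col not in df.columns or not len(df):
                continue
            stale = []
            for root in df[col].dropna().unique():
                node = self.graph.nodes.get(int(root))
                if node is None or not node.valid_at(t_q):
                    stale.append(int(root))
            if not stale:
                continue
            is_stale = df[col].isin(stale)
            new_roots = [self.graph.get_root(int(sv), t_q) if pd.notna(sv)
                         else pd.NA
                         for sv in df.loc[is_stale, f"{f}_supervoxel"]]
            df.loc[is_stale, col] = pd.array(new_roots, dtype="Int64")
        return df

    # -- joins ----------------------------------------------------------------

    def join_query(self, spec_a: QuerySpec, spec_b: QuerySpec,
                   join_on: tuple[str, str], live: bool = False) -> QueryResult:
        """Inner join of two filtered queries on a column pair.

        Reference tables join naturally on ``("target_id", "id")``.
        """
        run = self.live_query if live else self.query_snapshot
        ra, rb = run(spec_a), run(spec_b)
        ca, cb = join_on
        for col, res, spec in ((ca, ra, spec_a), (cb, rb, spec_b)):
            if col not in res.df.columns:
                raise InvalidFilterError(
                    f"join column {col!r} not in table {spec.table!r}")
        df = ra.df.merge(rb.df, left_on=ca, right_on=cb,
                         suffixes=("", f"_{spec_b.table}"))
        return QueryResult(df, truncated=ra.truncated or rb.truncated)

    # -- persistence ----------------------------------------------------------

    def save_snapshots(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        catalog = []
        for i, snap in enumerate(self.snapshots):
            sub = d / f"snapshot_{i:04d}_t{snap.t_snap}"
            sub.mkdir(exist_ok=True)
            for name, df in snap.tables.items():
                df.to_csv(sub / f"{name}.csv", index=False)
            catalog.append({"t_snap": snap.t_snap, "dir": sub.name,
                            "tables": sorted(snap.tables)})
        (d / "catalog.json").write_text(json.dumps(catalog, indent=2))

    def load_snapshots(self, directory) -> int:
        d = Path(directory)
        catalog_path = d / "catalog.json"
        if not catalog_path.exists():
            return 0
        for entry in json.loads(catalog_path.read_text()):
            tables = {}
            for name in entry["tables"]:
                df = pd.read_csv(d / entry["dir"] / f"{name}.csv")
                for col in df.columns:
                    if col.endswith(("_root", "_supervoxel")):
                        df[col] = df[col].astype("Int64")
                    elif col == "superseded_by":
                        df[col] = df[col].astype(object).where(
                            df[col].notna(), None)
                tables[name] = df
            self.snapshots.append(Snapshot(t_snap=entry["t_snap"],
                                           tables=tables))
        return len(self.snapshots)
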