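"""Schema-driven annotation tables with bound spatial points and versioned
rows.

A *schema* is an ordered list of typed fields; the key type is the bound
spatial point, a voxel coordinate that is automatically bound to the
supervoxel underneath it at insert time. Reference schemas instead carry a
``target_id`` field attaching extra columns to rows of another table.

Rows are never destroyed: insert stamps ``created``, deletion is virtual
(stamps ``deleted``), and an update is a delete plus an insert linked via
``superseded_by`` — so the visible set at any timestamp is a pure function
of the log, which is what materialization and time-travel queries rely on.
Timestamps come from the same logical clock as graph edits, giving a single
total order over segmentation and annotation events.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .config import INFINITY_T, LogicalClock
from .errors import (ConstraintError, InvalidArgumentError, NotFoundError,
                     SchemaError)

FIELD_TYPES = {"bound_spatial_point", "spatial_point", "float", "int",
               "string", "enum", "target_id"}


# ---------------------------------------------------------------------------
# Schemas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SchemaField:
    name: str
    type: str
    required: bool = True
    enum_values: tuple[str, ...] = ()


@dataclass(frozen=True)
class Schema:
    name: str
    fields: tuple[SchemaField, ...]

    def __post_init__(self):
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            raise SchemaError(f"schema {self.name!r} has duplicate field names")
        for f in self.fields:
            if f.type not in FIELD_TYPES:
                raise SchemaError(f"unknown field type {f.type!r}")
            if f.type == "enum" and not f.enum_values:
                raise SchemaError(f"enum field {f.name!r} needs enum_values")
        if not self.is_reference and not self.bound_point_fields:
            raise SchemaError(
                f"schema {self.name!r} needs at least one bound_spatial_point")

    @property
    def bound_point_fields(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields
                     if f.type == "bound_spatial_point")

    @property
    def point_fields(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields
                     if f.type in ("bound_spatial_point", "spatial_point"))

    @property
    def is_reference(self) -> bool:
        return any(f.type == "target_id" for f in self.fields)

    @classmethod
    def from_dict(cls, spec: dict) -> "Schema":
        return cls(name=spec["name"], fields=tuple(
            SchemaField(name=f["name"], type=f["type"],
                        required=f.get("required", True),
                        enum_values=tuple(f.get("enum_values", ())))
            for f in spec["fields"]))

    def to_dict(self) -> dict:
        return {"name": self.name, "fields": [
            {"name": f.name, "type": f.type, "required": f.required,
             **({"enum_values": list(f.enum_values)} if f.enum_values else {})}
            for f in self.fields]}


# Starter library mirroring the common community schemas: synapses between
# two neurons (two bound points + size), cell locations (nuclei), cell-type
# reference rows, and proofreading status flags.
BUILTIN_SCHEMAS = {s.name: s for s in (
    Schema("synapse", (
        SchemaField("pre_pt", "bound_spatial_point"),
        SchemaField("post_pt", "bound_spatial_point"),
        SchemaField("size", "float"))),
    Schema("cell_location", (
        SchemaField("pt", "bound_spatial_point"),)),
    Schema("cell_type_reference", (
        SchemaField("target_id", "target_id"),
        SchemaField("cell_type", "string"))),
    Schema("proofreading_status", (
        SchemaField("pt", "bound_spatial_point"),
        SchemaField("status", "enum", enum_values=(
            "clean", "extended", "error")))),
)}


class SchemaRegistry:
    def __init__(self, builtins: bool = True):
        self._schemas: dict[str, Schema] = dict(BUILTIN_SCHEMAS) if builtins else {}

    def register(self, schema: Schema) -> None:
        self._schemas[schema.name] = schema

    def get(self, name: str) -> Schema:
        if name not in self._schemas:
            raise NotFoundError(f"unknown schema {name!r}")
        return self._schemas[name]

    def load_json(self, path) -> Schema:
        schema = Schema.from_dict(json.loads(Path(path).read_text()))
        self.register(schema)
        return schema


# ---------------------------------------------------------------------------
# Rows and tables
# ---------------------------------------------------------------------------

@dataclass
class BoundPoint:
    position: tuple[int, int, int]
    supervoxel_id: Optional[int]    # None when the point is on background


@dataclass
class AnnotationRow:
    id: int
    values: dict
    created: int
    deleted: int = INFINITY_T
    superseded_by: Optional[int] = None

    def visible_at(self, t: int) -> bool:
        return self.created <= t < self.deleted


@dataclass
class TableMetadata:
    name: str
    schema_name: str
    description: str = ""
    reference_target: Optional[str] = None
    resolution: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass
class AnnotationTable:
    metadata: TableMetadata
    schema: Schema
    rows: dict[int, AnnotationRow] = dc_field(default_factory=dict)
    next_id: int = 1
    last_modified: int = 0


@dataclass
class InsertResult:
    ids: list[int]
    rejected: list[tuple[int, str]]   # (row position, reason)


# ---------------------------------------------------------------------------
# Store
# ---------------------------------------------------------------------------

class AnnotationStore:
    """Tables + registry + the shared logical clock.

    ``sv_resolver(point) -> supervoxel_id or None`` performs the automatic
    supervoxel lookup for bound points (None = background); it is typically
    wired to the label grid and the graph's supervoxel IDs.
    """

    def __init__(self, clock: Optional[LogicalClock] = None,
                 sv_resolver: Optional[Callable] = None,
                 registry: Optional[SchemaRegistry] = None):
        self.clock = clock or LogicalClock()
        self.sv_resolver = sv_resolver
        self.registry = registry or SchemaRegistry()
        self.tables: dict[str, AnnotationTable] = {}

    # -- tables -------------------------------------------------------------

    def create_table(self, name: str, schema_name: str, description: str = "",
                     reference_target: Optional[str] = None,
                     resolution=(1.0, 1.0, 1.0)) -> TableMetadata:
        if name in self.tables:
            raise InvalidArgumentError(f"table {name!r} already exists")
        schema = self.registry.get(schema_name)
        if schema.is_reference:
            if reference_target is None:
                raise ConstraintError(
                    f"schema {schema_name!r} is a reference schema; "
                    "reference_target is required")
            if reference_target not in self.tables:
                raise ConstraintError(
                    f"reference target table {reference_target!r} does not exist")
        meta = TableMetadata(name=name, schema_name=schema_name,
                             description=description,
                             reference_target=reference_target,
                             resolution=tuple(resolution))
        self.tables[name] = AnnotationTable(metadata=meta, schema=schema)
        return meta

    def _table(self, name: str) -> AnnotationTable:
        if name not in self.tables:
            raise NotFoundError(f"unknown table {name!r}")
        return self.tables[name]

    # -- validation + insert -------------------------------------------------

    def _validate_and_bind(self, table: AnnotationTable, raw: dict, t: int) -> dict:
        values = {}
        for f in table.schema.fields:
            if f.name not in raw:
                if f.required:
                    raise SchemaError(f"missing required field {f.name!r}")
                continue
            v = raw[f.name]
            if f.type in ("bound_spatial_point", "spatial_point"):
                pos = tuple(int(c) for c in v)
                if len(pos) != 3:
                    raise SchemaError(f"{f.name!r} must be a 3D point")
                if f.type == "bound_spatial_point":
                    sv = None
                    if self.sv_resolver is not None:
                        sv = self.sv_resolver(pos)   # may raise out-of-bounds
                    values[f.name] = BoundPoint(position=pos, supervoxel_id=sv)
                else:
                    values[f.name] = pos
            elif f.type == "float":
                values[f.name] = float(v)
            elif f.type in ("int", "target_id"):
                values[f.name] = int(v)
            elif f.type == "enum":
                if v not in f.enum_values:
                    raise SchemaError(
                        f"{f.name!r} must be one of {f.enum_values}, got {v!r}")
                values[f.name] = v
            else:
                values[f.name] = str(v)
        if table.schema.is_reference:
            target = self._table(table.metadata.reference_target)
            tid = values.get("target_id")
            row = target.rows.get(tid)
            if row is None or not row.visible_at(t):
                raise ConstraintError(
                    f"target_id {tid} not visible in "
                    f"{table.metadata.reference_target!r} at t={t}")
        return values

    def insert(self, table_name: str, rows, t: Optional[int] = None
               ) -> InsertResult:
        """Validate, bind supervoxels and insert; invalid rows are rejected
        individually and reported, valid rows are inserted."""
        table = self._table(table_name)
        t = self.clock.tick() if t is None else t
        result = InsertResult(ids=[], rejected=[])
        for i, raw in enumerate(rows):
            try:
                values = self._validate_and_bind(table, raw, t)
            except (SchemaError, ConstraintError, InvalidArgumentError) as e:
                result.rejected.append((i, str(e)))
                continue
            row = AnnotationRow(id=table.next_id, values=values, created=t)
            table.rows[row.id] = row
            table.next_id += 1
            result.ids.append(row.id)
        if result.ids:
            table.last_modified = max(table.last_modified, t)
        return result

    def delete(self, table_name: str, ids, t: Optional[int] = None) -> int:
        """Virtual delete: stamps ``deleted``; idempotent with a warning."""
        table = self._table(table_name)
        t = self.clock.tick() if t is None else t
        n = 0
        for rid in ids:
            row = table.rows.get(rid)
            if row is None:
                raise NotFoundError(f"row {rid} not in table {table_name!r}")
            if not row.visible_at(t):
                warnings.warn(f"row {rid} already deleted; no-op")
                continue
            row.deleted = t
            n += 1
        if n:
            table.last_modified = max(table.last_modified, t)
        return n

    def update(self, table_name: str, row_id: int, new_values: dict,
               t: Optional[int] = None) -> int:
        """Delete + insert with ``superseded_by`` linkage; returns the new id."""
        table = self._table(table_name)
        t = self.clock.tick() if t is None else t
        old = table.rows.get(row_id)
        if old is None or not old.visible_at(t):
            raise NotFoundError(f"row {row_id} not visible at t={t}")
        merged = {**self._unbind(table, old.values), **new_values}
        values = self._validate_and_bind(table, merged, t)
        old.deleted = t
        new = AnnotationRow(id=table.next_id, values=values, created=t)
        table.rows[new.id] = new
        table.next_id += 1
        old.superseded_by = new.id
        table.last_modified = max(table.last_modified, t)
        return new.id

    @staticmethod
    def _unbind(table: AnnotationTable, values: dict) -> dict:
        out = {}
        for k, v in values.items():
            out[k] = v.position if isinstance(v, BoundPoint) else v
        return out

    # -- queries ------------------------------------------------------------

    def visible_rows(self, table_name: str, t: int) -> list[AnnotationRow]:
        return [r for r in self._table(table_name).rows.values()
                if r.visible_at(t)]

    def to_dataframe(self, table_name: str, t: int,
                     flag_orphans: bool = True) -> pd.DataFrame:
        """Flattened view of the rows visible at ``t``.

        Bound point fields expand to ``{f}_x/_y/_z`` and ``{f}_supervoxel``
        (nullable). Visible reference rows whose target is no longer visible
        are flagged ``orphaned`` rather than cascaded.
        """
        table = self._table(table_name)
        records = []
        for row in sorted(self.visible_rows(table_name, t), key=lambda r: r.id):
            # as-of-t presentation: a visible row is by definition not yet
            # deleted or superseded at t, regardless of later log entries
            rec = {"id": row.id, "created": row.created,
                   "deleted": INFINITY_T, "superseded_by": None}
            for f in table.schema.fields:
                v = row.values.get(f.name)
                if isinstance(v, BoundPoint):
                    rec[f"{f.name}_x"], rec[f"{f.name}_y"], rec[f"{f.name}_z"] = \
                        v.position
                    rec[f"{f.name}_supervoxel"] = v.supervoxel_id
                elif f.type == "spatial_point" and v is not None:
                    rec[f"{f.name}_x"], rec[f"{f.name}_y"], rec[f"{f.name}_z"] = v
                else:
                    rec[f.name] = v
            records.append(rec)
        columns = ["id", "created", "deleted", "superseded_by"]
        for f in table.schema.fields:
            if f.type in ("bound_spatial_point", "spatial_point"):
                columns += [f"{f.name}_x", f"{f.name}_y", f"{f.name}_z"]
                if f.type == "bound_spatial_point":
                    columns += [f"{f.name}_supervoxel"]
            else:
                columns.append(f.name)
        df = pd.DataFrame(records, columns=columns)
        for f in table.schema.bound_point_fields:
            df[f"{f}_supervoxel"] = df[f"{f}_supervoxel"].astype("Int64")
        if flag_orphans and table.schema.is_reference and len(df):
            target = self._table(table.metadata.reference_target)
            df["orphaned"] = [
                not (tid in target.rows and target.rows[tid].visible_at(t))
                for tid in df["target_id"]]
        return df

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        catalog = {}
        for name, table in self.tables.items():
            records = []
            for row in table.rows.values():
                rec = {"id": row.id, "created": row.created,
                       "deleted": row.deleted,
                       "superseded_by": row.superseded_by,
                       "values": json.dumps(self._serializable(table, row))}
                records.append(rec)
            if records:
                pd.DataFrame(records).to_csv(d / f"{name}.csv", index=False)
            else:
                (d / f"{name}.csv").unlink(missing_ok=True)
            catalog[name] = {
                "metadata": vars(table.metadata) | {
                    "resolution": list(table.metadata.resolution)},
                "schema": table.schema.to_dict(),
                "next_id": table.next_id,
                "last_modified": table.last_modified,
            }
        (d / "tables.json").write_text(json.dumps(catalog, indent=2))

    @staticmethod
    def _serializable(table: AnnotationTable, row: AnnotationRow) -> dict:
        out = {}
        for k, v in row.values.items():
            if isinstance(v, BoundPoint):
                out[k] = {"position": list(v.position),
                          "supervoxel_id": v.supervoxel_id}
            elif isinstance(v, tuple):
                out[k] = list(v)
            else:
                out[k] = v
        return out

    def load(self, directory) -> None:
        d = Path(directory)
        catalog = json.loads((d / "tables.json").read_text())
        for name, info in catalog.items():
            schema = Schema.from_dict(info["schema"])
            self.registry.register(schema)
            meta = TableMetadata(**{**info["metadata"],
                                    "resolution": tuple(
                                        info["metadata"]["resolution"])})
            table = AnnotationTable(metadata=meta, schema=schema,
                                    next_id=info["next_id"],
                                    last_modified=info["last_modified"])
            csv_path = d / f"{name}.csv"
            if csv_path.exists():
                df = pd.read_csv(csv_path)
                for rec in df.to_dict("records"):
                    raw = json.loads(rec["values"])
                    values = {}
                    for f in schema.fields:
                        if f.name not in raw:
                            continue
                        v = raw[f.name]
                        if f.type == "bound_spatial_point":
                            sv = v["supervoxel_id"]
                            values[f.name] = BoundPoint(
                                tuple(v["position"]),
                                int(sv) if sv is not None else None)
                        elif f.type == "spatial_point":
                            values[f.name] = tuple(v)
                        else:
                            values[f.name] = v
                    sup = rec["superseded_by"]
                    table.rows[int(rec["id"])] = AnnotationRow(
                        id=int(rec["id"]), values=values,
                        created=int(rec["created"]), deleted=int(rec["deleted"]),
                        superseded_by=None if pd.isna(sup) else int(sup))
            self.tables[name] = table
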