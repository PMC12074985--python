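"""Configuration, NodeID bit layout, logical clock and structured logging.

The 64-bit NodeID packs ``[layer | x | y | z | counter]``; default widths
``8/12/12/12/20`` give graphene-style IDs with room for 4096 chunks per axis
and ~10^6 nodes per (layer, chunk). Timestamps are a logical integer clock:
0 is ingest and every edit or annotation event consumes a fresh value, which
makes version history exactly reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .errors import InvalidArgumentError

INFINITY_T = 2**62  # sentinel "never expires" timestamp


# ---------------------------------------------------------------------------
# NodeID packing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BitLayout:
    """Bit widths of the packed 64-bit NodeID, most-significant first."""

    layer_bits: int = 8
    x_bits: int = 12
    y_bits: int = 12
    z_bits: int = 12
    counter_bits: int = 20

    def __post_init__(self):
        total = (self.layer_bits + self.x_bits + self.y_bits + self.z_bits
                 + self.counter_bits)
        if total != 64:
            raise InvalidArgumentError(f"bit widths must sum to 64, got {total}")

    def pack(self, layer: int, chunk: tuple[int, int, int], counter: int) -> int:
        cx, cy, cz = chunk
        for name, val, bits in (("layer", layer, self.layer_bits),
                                ("x", cx, self.x_bits),
                                ("y", cy, self.y_bits),
                                ("z", cz, self.z_bits),
                                ("counter", counter, self.counter_bits)):
            if not (0 <= val < (1 << bits)):
                raise InvalidArgumentError(
                    f"NodeID field {name}={val} overflows {bits} bits")
        packed = layer
        packed = (packed << self.x_bits) | cx
        packed = (packed << self.y_bits) | cy
        packed = (packed << self.z_bits) | cz
        packed = (packed << self.counter_bits) | counter
        return packed

    def unpack(self, packed: int) -> tuple[int, tuple[int, int, int], int]:
        counter = packed & ((1 << self.counter_bits) - 1)
        rest = packed >> self.counter_bits
        cz = rest & ((1 << self.z_bits) - 1)
        rest >>= self.z_bits
        cy = rest & ((1 << self.y_bits) - 1)
        rest >>= self.y_bits
        cx = rest & ((1 << self.x_bits) - 1)
        rest >>= self.x_bits
        layer = rest & ((1 << self.layer_bits) - 1)
        return layer, (cx, cy, cz), counter

    def layer_of(self, packed: int) -> int:
        return packed >> (self.x_bits + self.y_bits + self.z_bits
                          + self.counter_bits)


# ---------------------------------------------------------------------------
# Logical clock
# ---------------------------------------------------------------------------

class LogicalClock:
    """Strictly increasing integer clock shared by graph edits and annotations.

    ``t = 0`` is reserved for ingest; :meth:`tick` hands out 1, 2, 3, ...
    """

    def __init__(self, start: int = 0):
        self._now = start

    @property
    def now(self) -> int:
        return self._now

    def tick(self) -> int:
        self._now += 1
        return self._now

    def advance_to(self, t: int) -> None:
        if t < self._now:
            raise InvalidArgumentError(f"clock cannot move backwards to {t}")
        self._now = t


# ---------------------------------------------------------------------------
# Project configuration
# ---------------------------------------------------------------------------

class ProjectConfig(BaseModel):
    """Tunables and paths for a microcave project.

    ``chunk_size`` is the voxel extent of one layer-2 chunk; ``fanout`` chunks
    are merged per dimension per layer going up the octree.
    """

    # paths (optional: in-memory use needs none)
    volume_path: Optional[Path] = None
    graph_dir: Optional[Path] = None
    cache_dir: Optional[Path] = None
    tables_dir: Optional[Path] = None
    snapshots_dir: Optional[Path] = None

    chunk_size: tuple[int, int, int] = (16, 16, 16)
    fanout: int = 2
    layer_bits: int = 8
    x_bits: int = 12
    y_bits: int = 12
    z_bits: int = 12
    counter_bits: int = 20

    # defaults
    invalidation_d: Optional[float] = None   # None -> 3x median edge weight
    row_limit: int = 500_000
    fake_edge_affinity: float = 1.0e6
    within_cell_affinity: tuple[float, float] = (0.9, 0.05)   # mean, sd
    false_merge_affinity: tuple[float, float] = (0.3, 0.10)   # mean, sd
    resolution: tuple[float, float, float] = (8.0, 8.0, 40.0)  # nm per voxel
    seed: int = 0

    @model_validator(mode="after")
    def _check_bits(self):
        total = (self.layer_bits + self.x_bits + self.y_bits + self.z_bits
                 + self.counter_bits)
        if total != 64:
            raise ValueError(f"NodeID bit widths must sum to 64, got {total}")
        if self.fanout < 2:
            raise ValueError("fanout must be >= 2")
        if any(c < 1 for c in self.chunk_size):
            raise ValueError("chunk_size entries must be >= 1")
        return self

    def bit_layout(self) -> BitLayout:
        return BitLayout(self.layer_bits, self.x_bits, self.y_bits,
                         self.z_bits, self.counter_bits)

    @classmethod
    def from_json(cls, path: str | Path) -> "ProjectConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


# ---------------------------------------------------------------------------
# Structured logging: JSON lines with op_id correlation
# ---------------------------------------------------------------------------

class JsonLineFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        payload = {
            "logger": record.name,
            "level": record.levelname,
            "msg": record.getMessage(),
        }
        for key in ("op_id", "t", "stage"):
            if hasattr(record, key):
                payload[key] = getattr(record, key)
        return json.dumps(payload, sort_keys=True)


def get_logger(name: str = "microcave") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(JsonLineFormatter())
        logger.addHandler(handler)
        logger.setLevel(logging.WARNING)
        logger.propagate = False
    return logger
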