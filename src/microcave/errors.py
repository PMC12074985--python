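"""Exception hierarchy shared across the package.

Errors carry enough state (IDs, timestamps, lineage successors) for callers
to recover programmatically — e.g. a :class:`StaleIDError` names the roots
that superseded the requested one.
"""

from __future__ import annotations


class MicrocaveError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MicrocaveError, ValueError):
    """A precondition on an argument was violated."""


class NotFoundError(MicrocaveError, KeyError):
    """A referenced node, supervoxel, table or row does not exist."""


class StaleIDError(MicrocaveError):
    """A root ID is not valid at the queried timestamp.

    ``successors`` holds the lineage successors (or predecessors) closest in
    time to the query, so callers can re-resolve.
    """

    def __init__(self, node_id: int, t: int, successors: tuple[int, ...] = ()):
        self.node_id = node_id
        self.t = t
        self.successors = successors
        msg = f"node {node_id} is not valid at t={t}"
        if successors:
            msg += f"; lineage successors: {sorted(successors)}"
        super().__init__(msg)


class NoOpEditError(MicrocaveError):
    """The requested edit would not change the segmentation."""


class InvalidSplitError(MicrocaveError):
    """Split labels do not resolve to a single root."""


class AmbiguousSplitError(MicrocaveError):
    """Label expansion made source and sink sets overlap; refine the labels."""


class NothingToCutError(MicrocaveError):
    """Sources and sinks are already disconnected in the local graph."""


class CutImpossibleError(MicrocaveError):
    """Every source-sink path runs through uncuttable edges."""


class ConcurrentEditError(MicrocaveError):
    """Another edit is in flight for an overlapping root; retry."""


class CacheMissError(MicrocaveError):
    """Morphology cache rows are missing for the listed L2 IDs."""

    def __init__(self, missing_ids):
        self.missing_ids = tuple(sorted(missing_ids))
        super().__init__(f"L2 cache rows missing for {len(self.missing_ids)} IDs: "
                         f"{list(self.missing_ids)[:5]}...")


class SchemaError(MicrocaveError):
    """Schema definition or row validation failure."""


class ConstraintError(MicrocaveError):
    """Reference-table integrity violation."""


class InvalidFilterError(MicrocaveError, ValueError):
    """A query filter references an unknown column or has a bad shape."""
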