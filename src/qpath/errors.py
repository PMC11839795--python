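"""Exception hierarchy.

Every failure mode the pipeline can hit maps to a distinct subclass so
callers (and the CLI) can react precisely; all inherit from
:class:`QPathError`.
"""


class QPathError(Exception):
    """Base class for all qpath errors."""


class InvalidSpecError(QPathError, ValueError):
    """A phantom or configuration spec violates its invariants."""


class RiskTableError(QPathError, ValueError):
    """Malformed risk table: duplicate conflicting names or out-of-range scores."""


class MissingScoreError(QPathError, KeyError):
    """A labelled segment has no score in the risk table and no default was given."""

    def __init__(self, names):
        self.names = sorted(names)
        super().__init__(f"no risk score for segment(s): {', '.join(self.names)}")


class FusionError(QPathError, ValueError):
    """Risk-volume layers cannot be fused (shape or spacing mismatch)."""


class GeometryError(QPathError, ValueError):
    """Degenerate or out-of-volume pathway geometry."""


class BoundsError(QPathError, IndexError):
    """A voxel index lies outside the grid."""


class NoTransitionError(QPathError, ValueError):
    """A Q-table update was requested on a non-adjacent (sentinel -1) pair."""


class UnreachableError(QPathError, RuntimeError):
    """No path exists from entry to target under the configured graph."""


class NonConvergenceError(QPathError, RuntimeError):
    """Greedy path extraction hit a cycle or dead end."""


class InvalidPathError(QPathError, ValueError):
    """A voxel path violates adjacency or uses a -1 transition."""


class VolumeIOError(QPathError, ValueError):
    """A volume file could not be interpreted (dtype, metadata, spacing)."""
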