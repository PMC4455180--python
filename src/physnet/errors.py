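"""Exception hierarchy shared across physnet modules."""


class PhysnetError(Exception):
    """Base class for all physnet errors."""


class DisconnectedGraphError(PhysnetError):
    """An operation that requires a connected graph received a disconnected one."""

    def __init__(self, message: str, components=None):
        super().__init__(message)
        self.components = components


class DegenerateGeometryError(PhysnetError):
    """City geometry is degenerate (coincident points, zero distances)."""


class SingularSystemError(PhysnetError):
    """The grounded pressure system is singular and cannot be solved."""
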