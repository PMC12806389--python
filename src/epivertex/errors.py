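"""Exception hierarchy for the vertex-model simulator."""


class EpivertexError(Exception):
    """Base class for all package errors."""


class InvalidCellError(EpivertexError):
    """A polygon cell violates a precondition (too few vertices, bad cycle)."""


class DegenerateEdgeError(EpivertexError):
    """An edge has (numerically) zero length where a direction is required."""


class StructuralInstabilityError(EpivertexError):
    """The mesh left the space of valid tessellations (non-finite state,
    crossed polygons).  The driver converts this into an ``unstable`` run
    label instead of letting it escape."""


class ConfigError(EpivertexError):
    """Invalid or unknown configuration value."""


class TopologyEventError(EpivertexError):
    """A division or intercalation cannot be applied to the current mesh."""
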