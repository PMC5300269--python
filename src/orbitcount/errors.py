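"""Exception types shared across the package."""


class OrbitCountError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedSizeError(OrbitCountError):
    """Raised when a graphlet size outside the supported 2..5 range is requested."""


class IdentificationError(OrbitCountError):
    """Raised when a small graph cannot be matched against the atlas
    (disconnected input, too many nodes, unknown orbit id)."""


class GraphInputError(OrbitCountError):
    """Raised for malformed host-graph input (bad header, self-loop,
    duplicate or out-of-range edge)."""


class IntegrityError(OrbitCountError):
    """Raised when an internal exactness witness fails, e.g. a triangular
    solve that does not divide exactly or produces a negative count.
    Indicates corrupted input or an internal defect, never a rounding issue."""


class OracleCapError(OrbitCountError):
    """Raised when the brute-force oracle refuses an instance whose projected
    subgraph count exceeds the configured cap."""
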