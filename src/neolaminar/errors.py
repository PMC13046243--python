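"""Exception hierarchy for neolaminar.

All errors derive from :class:`NeolaminarError` so callers can catch the
package's failures with a single except clause; each subclass marks the
contract that was violated.
"""


class NeolaminarError(Exception):
    """Base class for all neolaminar errors."""


class ParameterizationError(NeolaminarError, ValueError):
    """Simulation parameters are infeasible or out of their validated range."""


class GeometryError(NeolaminarError, ValueError):
    """A mesh or thickness field is geometrically invalid (e.g. self-intersection)."""


class TopologyError(NeolaminarError, ValueError):
    """Mesh connectivity violates a requirement (e.g. isolated vertex)."""


class ContractError(NeolaminarError, ValueError):
    """Inputs violate an interface contract (mismatched topology, misalignment...)."""


class CollinearityError(ContractError):
    """A design matrix is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class AlignmentError(ContractError):
    """Subject identifiers do not align between two tables."""


class DegenerateProfileError(NeolaminarError, ValueError):
    """A depth profile has no mass (all zero) or negative entries."""


class EmptyResultError(NeolaminarError, ValueError):
    """An aggregation produced no output (e.g. every parcel excluded)."""


class FormatError(NeolaminarError, ValueError):
    """A file on disk does not conform to the expected format."""


class NumericalError(NeolaminarError, RuntimeError):
    """An iterative numerical procedure failed to converge."""
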