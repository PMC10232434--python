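"""Exception hierarchy for river-network eDNA modelling."""


class RiverEdithError(Exception):
    """Base class for all package-specific errors."""


class TopologyError(RiverEdithError):
    """The reach graph is not a single-outlet rooted tree (cycle, multiple
    outlets, or disconnected components)."""


class ConnectivityError(RiverEdithError):
    """A path was requested between reaches that are not flow-connected in
    the required direction."""


class ReachLookupError(RiverEdithError, KeyError):
    """An unknown reach or site identifier was referenced."""


class ConfigError(RiverEdithError):
    """A run configuration is incomplete or inconsistent."""


class InsufficientDataError(RiverEdithError, ValueError):
    """Too few observations to carry out a fit or test."""


class SingularDischargeError(RiverEdithError):
    """Discharge is zero where a division by Q is required."""


class BinningError(RiverEdithError):
    """Drainage-area deciles produce an empty bin; the area distribution is
    too degenerate for the bootstrap trend test."""


class DiagnosticError(RiverEdithError):
    """A convergence diagnostic was requested on unsuitable chains."""


class UndefinedGroupError(RiverEdithError):
    """A location group yields no valid flow-unconnected pair in any
    replicate, so its Jaccard distribution is undefined."""


class InitializationError(RiverEdithError):
    """The sampler could not find a starting point with finite posterior
    density after the configured number of retries."""


class ValidationError(RiverEdithError, ValueError):
    """An input table violates its schema."""
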