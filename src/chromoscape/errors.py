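"""Exception hierarchy used across the package."""


class ChromoscapeError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ChromoscapeError, ValueError):
    """An argument violates an operation's precondition."""


class FormatError(ChromoscapeError, ValueError):
    """An input file is structurally invalid for the declared dialect."""


class ConfigurationError(ChromoscapeError, ValueError):
    """A configuration object is incomplete or inconsistent."""


class UndefinedResultError(ChromoscapeError, ValueError):
    """The requested quantity is mathematically undefined for this input."""


class SimulationError(ChromoscapeError, RuntimeError):
    """The integrator produced a non-finite state."""
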