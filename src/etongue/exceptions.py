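"""Exception hierarchy for the etongue package."""


class EtongueError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(EtongueError, ValueError):
    """Array shapes are inconsistent with the requested operation."""


class ParameterError(EtongueError, ValueError):
    """A configuration parameter is outside its admissible range."""


class DatasetError(EtongueError, ValueError):
    """A dataset violates a structural invariant (shape, order, labels)."""


class ProtocolError(EtongueError, ValueError):
    """A cross-validation protocol cannot be applied to the given dataset."""


class CapabilityError(EtongueError, RuntimeError):
    """A requested optional component (adapter, kernel) is unavailable."""


class NumericalError(EtongueError, RuntimeError):
    """A linear-algebra step failed beyond what regularization can absorb."""
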