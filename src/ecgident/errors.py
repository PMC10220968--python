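"""Exception hierarchy shared across the pipeline."""


class EcgIdentError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EcgIdentError, ValueError):
    """Malformed or out-of-contract data passed to an operation."""


class InvalidConfigError(EcgIdentError, ValueError):
    """Configuration violates a precondition (e.g. notch above Nyquist)."""


class DegenerateInputError(InvalidInputError):
    """Input is formally valid but carries no usable information
    (e.g. a constant record cannot be min-max normalized)."""


class InvalidStateError(EcgIdentError, RuntimeError):
    """Operation called on an object in the wrong state (e.g. unfitted model)."""


class GenerationError(EcgIdentError, RuntimeError):
    """Synthetic benchmark generation could not satisfy its guarantees."""
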