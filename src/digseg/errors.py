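"""Exception types shared across the pipeline."""


class DigsegError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DigsegError, ValueError):
    """A simulation or run configuration violates its invariants."""


class ValidationError(DigsegError, ValueError):
    """An input table or argument violates a data-model invariant."""
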