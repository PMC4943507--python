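"""Exception hierarchy shared across the package."""


class IEFSError(Exception):
    """Base class for all package errors."""


class FormatError(IEFSError):
    """A file does not conform to its declared dialect."""


class ValidationError(IEFSError):
    """An in-memory object or argument violates a documented invariant."""


class SamplingError(IEFSError):
    """A sampling operation cannot be performed on the given task."""


class FilterError(IEFSError):
    """A feature-selection operation produced no usable result."""


class PipelineError(IEFSError):
    """A multi-step fit failed; the message names the offending step."""
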