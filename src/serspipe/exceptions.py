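"""Exception hierarchy for serspipe."""


class SersPipeError(Exception):
    """Base class for all serspipe errors."""


class ValidationError(SersPipeError):
    """Input data violates an invariant (negative intensity, non-finite value, ...)."""


class ParseError(SersPipeError):
    """On-disk matrix could not be parsed (ragged rows, malformed cell)."""


class ParameterError(SersPipeError):
    """A stage parameter is outside its documented domain."""


class DegenerateDataError(SersPipeError):
    """Data is degenerate for the requested operation (zero-mean fragment,
    vanishing background channel, empty support, no overlap under any shift)."""
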