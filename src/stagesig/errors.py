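"""Exception hierarchy for the stagesig pipeline."""


class StagesigError(Exception):
    """Base class for all package errors."""


class ConfigError(StagesigError):
    """A configuration object violates one of its invariants.

    The message names the violated field.
    """


class ValidationError(StagesigError):
    """Runtime input fails a precondition (bad p-value, unknown label, ...)."""


class ParseError(StagesigError):
    """A text input file is malformed; the message carries the line number."""


class ContrastError(StagesigError):
    """A differential-expression contrast cannot be formed (e.g. < 2 samples)."""


class DegenerateDataError(StagesigError):
    """Data carry no usable variation (all-zero variance, all-equal coefficients)."""


class AnnotationError(StagesigError):
    """Probe-to-symbol annotation is inconsistent (conflicting duplicate probes)."""


class PipelineError(StagesigError):
    """A pipeline stage cannot proceed (e.g. empty round-1 selection)."""
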