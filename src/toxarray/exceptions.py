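"""Exception hierarchy shared across the pipeline."""


class ToxArrayError(Exception):
    """Base class for all toxarray errors."""


class ConfigurationError(ToxArrayError, ValueError):
    """A configuration field is invalid; the message names the field."""


class FormatError(ToxArrayError, ValueError):
    """An on-disk file does not match the expected format."""


class ValidationError(ToxArrayError, ValueError):
    """Parsed content violates a domain invariant."""


class EmptyResultError(ToxArrayError, RuntimeError):
    """An operation removed or received every record, leaving nothing to analyse."""


class DegenerateDataError(ToxArrayError, ValueError):
    """Input is degenerate for the requested statistic (e.g. zero variance)."""
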