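"""Exception hierarchy shared across the pipeline stages.

Every error raised on bad user input derives from :class:`OrsiteError`, so
callers (and the CLI) can distinguish validation problems (exit code 2) from
cross-input consistency problems (exit code 3).
"""


class OrsiteError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class FormatError(OrsiteError):
    """A file or text blob does not conform to its declared format."""

    exit_code = 2


class ValidationError(OrsiteError):
    """An input object or configuration violates its own invariants."""

    exit_code = 2


class ConsistencyError(OrsiteError):
    """Two or more inputs are individually valid but mutually inconsistent."""

    exit_code = 3
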