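"""Exception hierarchy for the DAS client stack.

All library errors derive from :class:`DastrackError` so callers (and the
CLI) can distinguish our failures from programming errors.  Transport
timeouts get their own retryable type because slow DAS servers are a fact
of life when requesting large regions of dense tracks.
"""

from __future__ import annotations


class DastrackError(Exception):
    """Base class for all errors raised by this package."""


class ArgumentError(DastrackError, ValueError):
    """A caller violated an operation's precondition."""


class CapabilityError(ArgumentError):
    """A DAS command was requested that the source does not advertise."""


class DasParseError(DastrackError):
    """A DAS XML document is not well formed.

    ``line`` carries the 1-based line number reported by the XML parser
    when available.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DasSchemaError(DastrackError):
    """Well-formed XML that is missing required DAS structure."""


class RecordValidationError(DastrackError):
    """A single DAS record violates an invariant (e.g. stop < start).

    Collected per record; one bad feature never blanks a whole document.
    """

    def __init__(self, record_id: str, message: str):
        self.record_id = record_id
        super().__init__(f"record {record_id!r}: {message}")


class ValidationError(DastrackError):
    """A domain object violates a model invariant."""


class PayloadVersionError(DastrackError):
    """A serialized payload or session declares an unknown format version."""


class TransportError(DastrackError):
    """Network-level failure talking to a DAS server."""

    retryable = False


class TransportTimeout(TransportError):
    """The DAS server did not answer within the configured timeout.

    Retryable: dense-track requests on busy servers time out routinely
    and often succeed on a second attempt or with a smaller window.
    """

    retryable = True


class ContainerError(DastrackError):
    """A track container was given tracks from mismatched segments."""
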