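"""Exception hierarchy shared across the package."""


class FurrowScanError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FurrowScanError, ValueError):
    """An argument violates an operation's precondition."""


class ParseError(FurrowScanError, ValueError):
    """A serialized message or record could not be decoded.

    ``offset`` is the byte offset at which decoding failed, when known.
    """

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)
        self.offset = offset


class ChecksumError(ParseError):
    """An NMEA sentence failed checksum validation."""


class LayoutError(FurrowScanError, ValueError):
    """A field layout description is internally inconsistent."""


class InitializationError(FurrowScanError, RuntimeError):
    """Soil-reference initialization could not be completed."""


class NoThresholdError(FurrowScanError, RuntimeError):
    """A histogram had no usable bimodal structure."""


class IntegrityError(FurrowScanError, ValueError):
    """Conflicting metadata between inputs that must agree."""
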