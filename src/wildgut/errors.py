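"""Exception hierarchy shared by all modules."""


class WildgutError(Exception):
    """Base class for all package errors."""


class FormatError(WildgutError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(WildgutError):
    """Well-formed input that violates a domain invariant."""


class UsageError(WildgutError):
    """An operation was called with arguments outside its contract."""


class InsufficientDataError(WildgutError):
    """Too few observations remain to run the requested analysis."""
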