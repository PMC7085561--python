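"""Exception hierarchy shared across the toolkit."""


class MsftError(Exception):
    """Base class for all toolkit errors."""


class TraceParseError(MsftError):
    """A trace CSV could not be parsed; the message names the offending line."""


class TraceOrderingError(MsftError):
    """Trace timestamps are not strictly increasing."""


class ValidationError(MsftError, ValueError):
    """A value violates a domain invariant (unit band, range, length...)."""


class ModeError(MsftError):
    """An operation was invoked on a test item of the wrong administration mode."""


class UndefinedStatisticError(MsftError):
    """A statistic is undefined for the given data (e.g. zero total variance)."""


class DataError(MsftError):
    """A packaged or user-supplied data table fails its integrity contract."""


class IntegrityError(MsftError):
    """A store operation violates referential integrity."""


class StoreLookupError(MsftError, KeyError):
    """A requested entity does not exist in the store."""
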