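"""Exception hierarchy shared across the package."""


class CossError(Exception):
    """Base class for all package errors."""


class AlignmentError(CossError):
    """Raised when well coordinates cannot be aligned to an ideal lattice."""


class DataError(CossError):
    """Raised for malformed or inconsistent input data."""


class UsageError(CossError):
    """Raised for invalid parameter values or call sequences."""
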