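"""Exception hierarchy shared across the package."""


class StsdelError(Exception):
    """Base class for all package errors."""


class FormatError(StsdelError):
    """A file does not conform to the expected tabular format."""


class ValidationError(StsdelError):
    """Input data violates a documented invariant."""


class ContractError(StsdelError):
    """An operation was invoked on data in the wrong state."""


class LookupError_(StsdelError):
    """An identifier is unknown to the catalog or matrix."""
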