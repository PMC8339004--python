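"""Exception types shared across the package."""


class CxrsimError(Exception):
    """Base class for package errors."""


class ValidationError(CxrsimError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(CxrsimError, ValueError):
    """A file does not parse under the named standard."""


class PlacementError(CxrsimError, RuntimeError):
    """A nodule could not be placed inside the lung mask."""
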