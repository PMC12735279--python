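"""Exception hierarchy shared across the pipeline stages."""


class VtePanelError(Exception):
    """Base class for all package errors."""


class FormatError(VtePanelError):
    """A file does not conform to its documented layout."""


class ValidationError(VtePanelError):
    """Well-formed input violates a domain invariant."""


class UsageError(VtePanelError):
    """An operation was called with an inconsistent argument combination."""


class DegenerateTableError(VtePanelError):
    """A contingency table carries no information for the requested estimate."""
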