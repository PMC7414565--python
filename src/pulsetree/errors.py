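"""Exception hierarchy shared across the package."""


class PulseTreeError(Exception):
    """Base class for all package errors."""


class NewickParseError(PulseTreeError):
    """Malformed newick input; message names the offending position."""


class ValidationError(PulseTreeError):
    """A domain object violates one of its invariants."""


class UltrametricityError(ValidationError):
    """Root-to-tip path lengths disagree beyond tolerance."""


class AssemblyError(PulseTreeError):
    """Backbone-and-patch assembly cannot be completed as specified."""


class DomainError(PulseTreeError, ValueError):
    """A numeric argument is outside its mathematical domain."""
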