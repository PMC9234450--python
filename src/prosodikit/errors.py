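"""Typed exceptions shared across the package.

Readers raise :class:`FormatError` for structurally malformed files and
:class:`ValidationError` for files that parse but violate a domain
invariant; numeric routines raise :class:`DomainError` for arguments
outside their mathematical domain.
"""


class ProsodikitError(Exception):
    """Base class for all package errors."""


class FormatError(ProsodikitError):
    """A file does not conform to its declared format."""


class ValidationError(ProsodikitError):
    """Parsed data violates a domain invariant (e.g. valence off-scale)."""


class DomainError(ProsodikitError):
    """A numeric argument is outside the mathematical domain of an operation."""


class ConfigError(ProsodikitError):
    """A configuration object is internally inconsistent or infeasible."""
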