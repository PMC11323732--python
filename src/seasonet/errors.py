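"""Exception hierarchy shared across the package."""


class SeasonetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SeasonetError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(SeasonetError):
    """Inputs are well-formed but violate a semantic precondition."""


class InsufficientDataError(SeasonetError):
    """Too few rows/columns survive filtering for the requested analysis."""
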