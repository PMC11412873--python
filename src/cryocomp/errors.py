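"""Exception types shared across the package."""


class CryocompError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CryocompError, ValueError):
    """A file does not conform to its expected format."""


class DegenerateInputError(CryocompError, ValueError):
    """Input is syntactically valid but too degenerate to analyze."""
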