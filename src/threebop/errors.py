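"""Exception hierarchy."""


class ThreeBOPError(Exception):
    """Base class for package errors."""


class FormatError(ThreeBOPError, ValueError):
    """Malformed or empty input file."""


class StructureError(ThreeBOPError, ValueError):
    """Invalid or incomplete molecular structure."""


class ParameterError(ThreeBOPError, ValueError):
    """Invalid numeric or scheme parameter."""


class UsageError(ThreeBOPError, ValueError):
    """API misuse: inconsistent arguments, missing positions, bad names."""
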