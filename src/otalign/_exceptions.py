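"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage errors exit 2 (argparse),
:class:`ValidationError` exits 3, :class:`NumericalError` exits 4.
"""


class OTAlignError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OTAlignError):
    """Malformed, inconsistent, or non-finite input data."""


class ParameterError(OTAlignError):
    """A parameter is outside its admissible range."""


class NumericalError(OTAlignError):
    """An iterative routine diverged or produced non-finite values."""
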