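"""Exception hierarchy shared across the package."""


class LovkitError(Exception):
    """Base class for all package-specific errors."""


class InputError(LovkitError, ValueError):
    """Invalid user input (bad alphabet, shapes, values out of domain)."""


class ParseError(LovkitError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class DegenerateDataError(LovkitError, ValueError):
    """Data are structurally valid but carry no usable signal
    (constant trace, all-gap pair, non-positive band maximum)."""


class FitError(LovkitError, RuntimeError):
    """A nonlinear fit failed to converge or is unresolvable."""
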