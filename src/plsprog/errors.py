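"""Exception hierarchy shared across the package."""


class PlsprogError(Exception):
    """Base class for package-specific failures."""


class ValidationError(PlsprogError, ValueError):
    """Invalid input: shape mismatch, duplicate identifiers, bad parameter."""


class ParseError(PlsprogError, ValueError):
    """A text input file could not be parsed; message carries the line."""


class RankError(PlsprogError, ArithmeticError):
    """Deflation exhausted the data before the requested latent variable."""


class NumericalError(PlsprogError, ArithmeticError):
    """A linear solve or iteration failed numerically."""


class ConvergenceError(NumericalError):
    """An iterative fit diverged or hit its iteration budget."""
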