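"""Exception hierarchy shared across the package."""


class Lacto2dError(Exception):
    """Base class for all package-specific errors."""


class FormatError(Lacto2dError):
    """Malformed input file (ragged rows, unparseable header, ...)."""


class GridError(Lacto2dError):
    """Wavelength grid is invalid or two grids do not match."""


class UniquenessError(Lacto2dError):
    """Duplicate sample identifiers."""


class StratificationError(Lacto2dError):
    """A class is too small to stratify the requested split."""


class DegenerateInputError(Lacto2dError):
    """Input is degenerate for the requested operation (e.g. constant spectrum)."""


class ConfigError(Lacto2dError):
    """Invalid configuration value."""


class LabelError(Lacto2dError):
    """Unknown or out-of-scheme class label / acidity value."""


class NumericalError(Lacto2dError):
    """Numerical failure (singular matrix, non-convergence)."""
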