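"""Exception types shared across the toolkit."""


class CiukitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(CiukitError, ValueError):
    """A structure or table file could not be parsed."""


class EmptyInputError(CiukitError, ValueError):
    """An input contained no usable records."""


class MissingAnchorError(CiukitError, ValueError):
    """An ionizable residue lacks the atom that carries its site charge."""


class ConfigMismatchError(CiukitError, ValueError):
    """A charge configuration does not belong to the given site list."""


class InfeasibleChargeError(CiukitError, ValueError):
    """The requested net charge cannot be realized on the site inventory."""


class UnknownElementError(CiukitError, KeyError):
    """An element symbol is missing from the hard-sphere radii table."""


class CalibrationDomainError(CiukitError, ValueError):
    """A drift time or corrected drift time left the calibration domain."""
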