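"""Exception types shared across the package."""


class LigandsweepError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(LigandsweepError, ValueError):
    """An argument violates a documented precondition."""


class LengthError(InvalidArgumentError):
    """Peptide length outside the supported range."""


class AlphabetError(InvalidArgumentError):
    """Sequence contains a residue outside the 20 canonical amino acids."""


class ConfigurationError(LigandsweepError):
    """A profile or run configuration is incomplete or inconsistent."""


class UndefinedStatisticError(LigandsweepError):
    """A statistic is undefined for the given input (e.g. zero hits)."""
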