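"""Exception hierarchy.

Warnings never abort a run; validation and format errors always do.
"""


class AuxIAAError(Exception):
    """Base class for all package errors."""


class FormatError(AuxIAAError):
    """Malformed input file (bad FASTA header, empty file, ...)."""


class SchemaError(AuxIAAError):
    """A delimited table is missing required columns."""


class ValidationError(AuxIAAError):
    """Input violates a documented invariant (e.g. asymmetric paralogs)."""


class InputError(AuxIAAError):
    """Invalid characters or values in a sequence or observation."""


class CoordinateError(AuxIAAError):
    """Genomic coordinates outside the supplied chromosome."""


class InsufficientDataError(AuxIAAError):
    """Too few observations for the requested fit or test."""


class UndefinedStatisticError(AuxIAAError):
    """A statistic has no defined value (zero variance, all censored)."""


class ParameterError(AuxIAAError):
    """Inconsistent or out-of-range simulation/configuration parameters."""
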