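"""Exception hierarchy for the turnover pipeline."""


class HWTurnoverError(Exception):
    """Base class for all package-specific errors."""


class InvalidSequenceError(HWTurnoverError, ValueError):
    """A peptide sequence contains a character that is not a standard residue code."""


class ConfigurationError(HWTurnoverError, ValueError):
    """A configuration table (isotope abundances, labelling sites, pipeline config) is invalid."""


class DomainError(HWTurnoverError, ValueError):
    """A numeric argument is outside the mathematically valid domain."""


class InsufficientDataError(HWTurnoverError, ValueError):
    """Too few observations to attempt the requested fit or test."""


class FitFailureError(HWTurnoverError, RuntimeError):
    """The optimiser failed to converge; the message carries the diagnostic."""


class SchemaError(HWTurnoverError, ValueError):
    """An input table does not match the documented CSV schema."""


class ParseError(HWTurnoverError, ValueError):
    """A row in an input table could not be parsed; the message names the line."""


class PairingError(HWTurnoverError, ValueError):
    """Paired inputs could not be matched one-to-one."""


class EmptyProteinError(HWTurnoverError, ValueError):
    """A protein has no accepted peptide fits to aggregate."""
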