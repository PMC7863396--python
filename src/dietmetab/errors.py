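"""Exception hierarchy shared across the pipeline."""


class DietMetabError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DietMetabError):
    """A configuration value is missing, malformed, or inconsistent."""


class InputError(DietMetabError):
    """Caller-supplied data violates a precondition."""


class DataError(DietMetabError):
    """Data values are internally inconsistent (e.g. all-zero ion)."""


class UnitError(InputError):
    """A measurement was supplied in the wrong unit."""


class OutOfRangeError(InputError):
    """A query falls outside the covered span of a reference table."""


class DegenerateDesignError(InputError):
    """A regression design matrix is rank deficient."""


class FeasibilityError(InputError):
    """An exhaustive computation was requested but is infeasible."""


class FormatError(InputError):
    """A string (e.g. an elemental formula) could not be parsed."""
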