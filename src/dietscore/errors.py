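"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`DietScoreError`, so callers can catch one type at pipeline
boundaries while tests assert on the specific subclass.
"""


class DietScoreError(Exception):
    """Base class for all dietscore errors."""


class DefinitionNotFoundError(DietScoreError, KeyError):
    """Requested index definition does not exist."""


class ParameterError(DietScoreError, ValueError):
    """A scoring-rule or function parameter is inconsistent."""


class ProfileValidationError(DietScoreError, ValueError):
    """An intake profile does not match an index definition.

    Carries the offending component ids so callers can report them.
    """

    def __init__(self, message, missing=(), extra=()):
        super().__init__(message)
        self.missing = tuple(missing)
        self.extra = tuple(extra)


class RangeError(DietScoreError, ValueError):
    """A value lies outside its theoretical bounds."""


class PairingError(DietScoreError, ValueError):
    """Gender strata cannot be paired by country."""


class CrosswalkError(DietScoreError, ValueError):
    """A crosswalk references unknown components or is malformed."""


class TaggingError(CrosswalkError):
    """A meat source category lacks a species/processed tag."""


class CoefficientError(DietScoreError, KeyError):
    """An added-sugar coefficient is missing for a contributing category."""


class SchemaError(DietScoreError, ValueError):
    """A delimited input file does not match the expected schema."""


class ClusteringError(DietScoreError, ValueError):
    """Invalid clustering input (asymmetric matrix, bad k, ...)."""


class IncomparablePairError(ClusteringError):
    """Two units share no comparable variable for Gower's distance."""
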