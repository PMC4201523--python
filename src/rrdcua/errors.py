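"""Exception hierarchy for the cost-utility analysis pipeline."""


class CuaError(Exception):
    """Base class for all package errors."""


class SchemaError(CuaError):
    """A required column or field is missing from an input file."""


class CohortValidationError(CuaError):
    """A record violates a field invariant (utility bounds, negative cost, ...)."""


class LifeTableError(CuaError):
    """A life table violates its structural invariants or cannot resolve a lookup."""


class DomainError(CuaError, ValueError):
    """A numeric argument is outside the domain of an operation."""


class AnalysisError(CuaError):
    """An analysis-level precondition failed (empty cohort, empty scenario, ...)."""
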