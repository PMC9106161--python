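"""Exception hierarchy for the ACTE-MTB toolkit."""


class ActeMtbError(Exception):
    """Base class for all package errors."""


class ConfigError(ActeMtbError):
    """A rubric/survey config file could not be parsed.

    Carries line context from the YAML parser when available.
    """


class RubricValidationError(ActeMtbError):
    """A rubric violated one or more structural invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations)
        super().__init__(f"rubric failed validation: {lines}")


class ScoringError(ActeMtbError):
    """A response could not be translated into points."""


class CohortError(ActeMtbError):
    """A cohort-level operation failed (stratification, statistics, IO)."""
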