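"""Exception hierarchy for the cohort store and its engines."""


class CohortFusionError(Exception):
    """Base class for all package errors."""


class StoreError(CohortFusionError):
    """Problems loading, writing or validating a fused store."""


class StoreIntegrityError(StoreError):
    """Referential-integrity failure; carries the offending rows."""

    def __init__(self, message, violations=None):
        super().__init__(message)
        self.violations = list(violations or [])


class ReferenceError_(StoreError):
    """Malformed packaged reference data (duplicate rs numbers etc.)."""


class QuerySchemaError(CohortFusionError):
    """A query leaf references an unknown source or field."""


class QueryEvaluationError(CohortFusionError):
    """A criterion could not be applied (e.g. ordering op on text)."""


class AuthorizationError(CohortFusionError):
    """Caller lacks the privilege required for the operation."""


class NotFoundError(CohortFusionError):
    """A coded identifier is absent from the coding key."""


class KeyIntegrityError(CohortFusionError):
    """The identifier-to-token mapping is not a bijection."""


class MessageError(CohortFusionError):
    """ACPA message failed schema validation or parsing."""

    def __init__(self, message, detail=None):
        super().__init__(message)
        self.detail = detail
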