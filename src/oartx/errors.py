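"""Exception hierarchy for the oartx toolkit."""


class OartxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OartxError):
    """Invalid configuration value (bad probability, unset institution, ...)."""


class AuthError(OartxError):
    """Authentication against the plan-check source failed."""


class ConnectionFailedError(OartxError):
    """Source endpoint unreachable after retries."""


class MissingCheckError(OartxError):
    """Requested check ID does not exist at the source."""


class ParseError(OartxError):
    """A source document could not be parsed; names the offending field."""


class MalformedPlanNameError(OartxError):
    """Plan name carries a SCH/ADP token but violates the naming grammar."""


class EmptyDVHError(OartxError):
    """A DVH was requested from an empty point list."""


class DomainError(OartxError):
    """Numeric argument outside its documented domain."""


class MissingReferenceError(OartxError):
    """Course has no reference plan; baseline-relative metrics unavailable."""


class MergeConflictError(OartxError):
    """Two cohorts disagree on rows for the same (uid, plan, structure) key."""


class IntegrityError(OartxError):
    """Store key collision across distinct source patients."""
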