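"""Exception hierarchy for storeflux.

Every error raised by the library derives from :class:`StorefluxError`,
so callers can catch one base class at pipeline boundaries.
"""


class StorefluxError(ValueError):
    """Base class for all storeflux errors."""


class SchemaError(StorefluxError):
    """A file does not match the documented column/field schema."""


class IntegrityError(StorefluxError):
    """Data violate a panel or registry invariant."""


class ConfigError(StorefluxError):
    """A simulation or pipeline configuration field is invalid."""


class CohortError(StorefluxError):
    """A cohort cannot be formed (e.g. empty baseline)."""


class PendingConsensusError(StorefluxError):
    """Dual-review disagreements lack a resolution."""


class EmptySubgroupError(StorefluxError):
    """No app qualifies for a requested subgroup."""


class UndefinedIntervalError(StorefluxError):
    """Removal interval is undefined because no removals occurred."""
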