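"""Exception hierarchy for strainsync.

All package errors derive from :class:`StrainSyncError` so callers can
catch one base class; subclasses distinguish file-format problems from
data-integrity violations and from misuse of an API contract.
"""


class StrainSyncError(Exception):
    """Base class for all strainsync errors."""


class FormatError(StrainSyncError):
    """A file does not follow the strainsync-v1 CSV dialect."""


class IntegrityError(StrainSyncError):
    """Data violates a structural invariant (duplicates, ragged traces, ...)."""


class CompletenessError(StrainSyncError):
    """An operation requires a complete layer (48 traces) and got fewer."""


class CycleDetectionError(StrainSyncError):
    """No cardiac cycle could be detected in a strain curve."""


class DataError(StrainSyncError):
    """A curve or vector is numerically unusable (all-NaN, zero norm)."""


class DomainError(StrainSyncError):
    """An argument lies outside the mathematical domain of an operation."""


class UsageError(StrainSyncError):
    """An API contract was violated (wrong count, empty input, ...)."""


class CapabilityError(StrainSyncError):
    """The study lacks data (e.g. point positions) the operation needs."""
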