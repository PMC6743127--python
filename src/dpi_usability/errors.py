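"""Exception hierarchy for the usability pipeline."""


class GUSError(Exception):
    """Base class for all package errors."""


class InvalidSchemeError(GUSError):
    """A scoring scheme violates one of its structural invariants."""


class MissingAnswerError(GUSError):
    """A questionnaire answer required by the scheme is absent (no imputation)."""


class DesignViolationError(GUSError):
    """A respondent reports a device outside their group's device set."""


class DuplicateObservationError(GUSError):
    """The same (respondent, device) pair appears more than once."""


class DisconnectedNetworkError(GUSError):
    """The evidence network is not connected, so a joint model is unidentifiable."""


class RecordIntegrityError(GUSError):
    """A record file fails validation (unknown device, total != sum of sub-scores...)."""
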