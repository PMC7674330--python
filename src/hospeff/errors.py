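"""Exception hierarchy for the hospeff package."""


class HospeffError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(HospeffError, ValueError):
    """An argument violates a documented precondition."""


class DataIntegrityError(HospeffError, ValueError):
    """Input tables are inconsistent (unresolvable codes, missing fields)."""


class InsufficientDataError(HospeffError, ValueError):
    """Too few observations to estimate the requested model."""


class NumericalError(HospeffError, RuntimeError):
    """A solver or optimizer failed where failure signals a defect."""
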