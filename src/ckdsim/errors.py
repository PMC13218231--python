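"""Exception hierarchy for ckdsim."""


class CkdSimError(Exception):
    """Base class for all ckdsim errors."""


class DomainError(CkdSimError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class ContractViolationError(CkdSimError, RuntimeError):
    """A precondition of an operation was violated by the caller."""


class EligibilityError(CkdSimError, ValueError):
    """A patient is not eligible for the requested treatment action."""


class ScheduleLookupError(CkdSimError, KeyError):
    """A cost/utility schedule is missing a required state or event key."""


class CalibrationError(CkdSimError, RuntimeError):
    """A calibration target could not be bracketed or reached."""
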