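"""Exception hierarchy for clockvar."""


class ClockvarError(Exception):
    """Base class for all clockvar errors."""


class SchemaError(ClockvarError):
    """A required column is missing or has the wrong type."""


class ValidationError(ClockvarError):
    """A table row violates an invariant (negative count, bad volume, ...)."""


class EmptyInputError(ClockvarError):
    """An input table or group collection is empty."""


class DegenerateStatisticError(ClockvarError):
    """A statistic is undefined on this input (e.g. zero mean expression)."""
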