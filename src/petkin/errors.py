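"""Exception hierarchy for petkin."""


class PetkinError(Exception):
    """Base class for all petkin errors."""


class InvalidArgumentError(PetkinError, ValueError):
    """An argument violates a documented precondition."""


class DataError(PetkinError, ValueError):
    """Input data violate an invariant (non-monotone times, zero blood, ...)."""


class FormatError(PetkinError, ValueError):
    """A delimited text file is malformed (missing columns, bad line)."""


class FitError(PetkinError, RuntimeError):
    """A model fit failed to converge or is degenerate."""
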