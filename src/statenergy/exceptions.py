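"""Exception types shared across the pipeline."""


class StatenergyError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StatenergyError, ValueError):
    """A configuration or call parameter violates a precondition."""


class DegenerateInputError(StatenergyError, ValueError):
    """Input data is degenerate (zero variance, all-zero matrix, ...)."""


class ContractViolationError(StatenergyError, ValueError):
    """An inter-stage contract was violated (e.g. non-z-scored input)."""
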