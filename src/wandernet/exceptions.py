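"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter value violates a documented precondition."""


class DegenerateInputError(ValueError):
    """Input data is degenerate for the requested operation.

    Examples: a zero-variance column when unit scaling is requested, a
    constant time series passed to a correlation, an all-zero data block.
    """


class DesignError(ValueError):
    """A GLM design matrix is unusable (rank deficient, misaligned rows...)."""
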