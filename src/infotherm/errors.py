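"""Exception types shared across the package."""


class ContractError(ValueError):
    """An argument violates a documented precondition."""


class SingularCovarianceError(ValueError):
    """A covariance matrix required to be positive definite is not.

    The message names the offending matrix so callers can tell which
    input (forward joint, swapped joint, marginal block, ...) failed.
    """


class ParseError(ValueError):
    """A series file is malformed; the message carries the line number."""
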