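"""Exception types shared across the toolkit."""


class DataError(ValueError):
    """Malformed, inconsistent or out-of-contract input data."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message, residual=None, step=None):
        super().__init__(message)
        self.residual = residual
        self.step = step
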