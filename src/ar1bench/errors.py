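"""Exception types shared across the package."""


class StationarityError(ValueError):
    """Raised when an autoregressive parameter lies outside the stationary region."""


class DegenerateSeriesError(ValueError):
    """Raised when a series is too short, non-finite, or has zero variance."""


class StepAdaptationError(RuntimeError):
    """Raised when Metropolis step-size adaptation fails to accept any proposal."""
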