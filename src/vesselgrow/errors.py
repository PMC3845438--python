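"""Exception types shared across the pipeline."""


class InvalidParameterError(ValueError):
    """A parameter violates an operation's precondition."""


class NoVesselError(RuntimeError):
    """Seed selection was requested on an ROI with no detected vessel."""


class SeedNotFoundError(RuntimeError):
    """Every candidate seed coincided with an edge pixel."""


class InvalidSeedError(ValueError):
    """The growing seed fails its own acceptance test."""
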