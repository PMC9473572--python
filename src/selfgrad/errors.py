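"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A model, grid, or binning configuration is invalid."""


class StabilityError(RuntimeError):
    """A numerical stability bound (CFL or sink rate) is violated."""


class ConsistencyError(RuntimeError):
    """An internal invariant (positivity, conservation) failed beyond round-off."""


class DegenerateInputError(ValueError):
    """Input data are degenerate for the requested measurement (e.g. constant
    intensity profile, zero-length track, empty mask after erosion)."""
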