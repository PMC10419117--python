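"""Exception types for invalid configurations and degenerate inputs."""


class ConfigurationError(ValueError):
    """A scenario, policy or trial configuration is invalid."""


class PositivityError(ValueError):
    """A propensity score lies outside (0, 1), violating positivity."""


class DegenerateProblemError(ValueError):
    """A weighted classification problem has no usable observations."""
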