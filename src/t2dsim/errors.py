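"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A user-supplied specification or config is structurally invalid."""


class SimulationError(RuntimeError):
    """Inputs to a simulation stage are mutually inconsistent."""
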