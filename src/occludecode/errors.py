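"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid or inconsistent user-supplied configuration."""


class ConvergenceError(RuntimeError):
    """An iterative procedure failed to reach its target within budget."""
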