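"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Invalid generator, smoothing, DTW, or model configuration."""


class TraceError(ValueError):
    """Malformed or degenerate fundamental-frequency trace."""


class ConvergenceError(RuntimeError):
    """MCMC diagnostics exceeded their thresholds (split R-hat > 1.01)."""
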